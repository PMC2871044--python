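"""Misincorporation spectra, damage frequency and endogenous-vs-contaminant
damage contrast.

Post-mortem cytosine deamination reads out as C->T (or G->A on the other
strand): "type II" transitions.  A->G / T->C are "type I"; the remaining
eight substitution classes are transversions.  Two conventions matter:

* clones of one amplification descend from the same few template molecules,
  so identical mismatches within one amplicon are a single molecular event —
  spectra are computed on events deduplicated per amplicon, with susceptible
  sites likewise counted once per amplicon;
* the per-site-per-sequence damage frequency instead keeps every sequence's
  events and normalizes by GC sites summed over sequences.

Both statistics correct for nucleotide composition by normalizing each class
by its own susceptible-site count (GC sites for type II, AT for type I, all
surveyed sites for transversions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignedSequence, SubstitutionEvent
from .loci import Amplicon, LocusSpec

TS_I = {("A", "G"), ("T", "C")}
TS_II = {("C", "T"), ("G", "A")}
SUB_TYPES = [(r, o) for r in "ACGT" for o in "ACGT" if r != o]


def substitution_class(ref: str, obs: str) -> str:
    if (ref, obs) in TS_II:
        return "TsII"
    if (ref, obs) in TS_I:
        return "TsI"
    return "Tv"


class SpectrumError(ValueError):
    pass


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def dedup_events(events: Iterable[SubstitutionEvent]) -> list[SubstitutionEvent]:
    """Collapse repeated events within one amplicon to single molecular events.

    Events sharing ``(amplicon_id, gene_pos, obs_base)`` collapse to one,
    however many clones of that amplicon show them; events from different
    amplicons, or with different derived bases, never collapse.  Output is
    sorted, so the operation is idempotent and order-invariant.
    """
    kept: dict[tuple[str, int, str], SubstitutionEvent] = {}
    for ev in events:
        key = (ev.amplicon_id, ev.gene_pos, ev.obs_base)
        if key not in kept:
            kept[key] = ev
    return sorted(kept.values(),
                  key=lambda e: (e.amplicon_id, e.gene_pos, e.obs_base))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass
class MisincorporationSpectrum:
    """Deduplicated substitution-type counts with composition-corrected
    per-site probabilities and percentage shares."""

    counts: dict[tuple[str, str], int]
    surveyed_at: int
    surveyed_gc: int
    surveyed_total: int
    label: str = ""

    @property
    def e_tsi(self) -> int:
        return sum(self.counts[t] for t in TS_I)

    @property
    def e_tsii(self) -> int:
        return sum(self.counts[t] for t in TS_II)

    @property
    def e_tv(self) -> int:
        return sum(v for t, v in self.counts.items()
                   if t not in TS_I and t not in TS_II)

    @property
    def n_events(self) -> int:
        return sum(self.counts.values())

    @property
    def p_tsi(self) -> float:
        return self.e_tsi / self.surveyed_at if self.surveyed_at else 0.0

    @property
    def p_tsii(self) -> float:
        return self.e_tsii / self.surveyed_gc if self.surveyed_gc else 0.0

    @property
    def p_tv(self) -> float:
        return self.e_tv / self.surveyed_total if self.surveyed_total else 0.0

    def _pct(self, p: float) -> float:
        denom = self.p_tsi + self.p_tsii + self.p_tv
        return 100.0 * p / denom if denom > 0 else 0.0

    @property
    def pct_tsi(self) -> float:
        return self._pct(self.p_tsi)

    @property
    def pct_tsii(self) -> float:
        return self._pct(self.p_tsii)

    @property
    def pct_tv(self) -> float:
        return self._pct(self.p_tv)


def _amplicon_composition(amplicon: Amplicon, locus: LocusSpec) -> tuple[int, int]:
    """(n_AT, n_GC) over the unmasked interior reference of one amplicon."""
    n_at = n_gc = 0
    for pos in locus.interior_positions(amplicon):
        if locus.ref_base(pos) in "AT":
            n_at += 1
        else:
            n_gc += 1
    return n_at, n_gc


def spectrum(deduped: Sequence[SubstitutionEvent],
             amplifications: Sequence[tuple[str, Amplicon]],
             locus: LocusSpec, label: str = "") -> MisincorporationSpectrum:
    """Composition-corrected spectrum from deduplicated events.

    ``amplifications`` lists every amplification instance surveyed as
    ``(amplicon_id, amplicon_design)`` — susceptible sites are counted once
    per amplification, matching the dedup convention for the numerators.
    """
    ids = {aid for aid, _ in amplifications}
    for ev in deduped:
        if ev.amplicon_id not in ids:
            raise SpectrumError(
                f"event at {ev.gene_pos} from unlisted amplicon {ev.amplicon_id!r}")
    counts = {t: 0 for t in SUB_TYPES}
    for ev in deduped:
        counts[(ev.ref_base, ev.obs_base)] += 1
    n_at = n_gc = 0
    for _, amp in amplifications:
        a, g = _amplicon_composition(amp, locus)
        n_at += a
        n_gc += g
    spec = MisincorporationSpectrum(counts=counts, surveyed_at=n_at,
                                    surveyed_gc=n_gc,
                                    surveyed_total=n_at + n_gc, label=label)
    if spec.e_tsii and not n_gc:
        raise SpectrumError("type-II events but zero surveyed GC sites")
    if spec.e_tsi and not n_at:
        raise SpectrumError("type-I events but zero surveyed AT sites")
    if spec.e_tv and not (n_at + n_gc):
        raise SpectrumError("transversion events but zero surveyed sites")
    return spec


def pool_spectra(spectra: Sequence[MisincorporationSpectrum],
                 label: str = "pooled") -> MisincorporationSpectrum:
    """Pool spectra by summing event and susceptible-site counts.

    Equivalent to recomputing the spectrum on the concatenated event lists;
    probabilities are therefore weighted by susceptible sites surveyed.
    """
    if not spectra:
        raise SpectrumError("pool_spectra: empty input")
    counts = {t: 0 for t in SUB_TYPES}
    for s in spectra:
        for t, v in s.counts.items():
            counts[t] += v
    return MisincorporationSpectrum(
        counts=counts,
        surveyed_at=sum(s.surveyed_at for s in spectra),
        surveyed_gc=sum(s.surveyed_gc for s in spectra),
        surveyed_total=sum(s.surveyed_total for s in spectra),
        label=label)


# ---------------------------------------------------------------------------
# damage frequency (per site per sequence; no deduplication)
# ---------------------------------------------------------------------------

def damage_frequency(events: Iterable[SubstitutionEvent],
                     aligned: Sequence[AlignedSequence]) -> float:
    """Type-II events per surveyed GC site, summed over every sequence.

    Events are NOT deduplicated here: this is the per-site-per-sequence
    damage rate, whose composition correction is inherited from the GC-site
    denominator.
    """
    if not aligned:
        raise SpectrumError("damage_frequency: no aligned sequences")
    gc_total = sum(a.surveyed_site_counts()[1] for a in aligned)
    if gc_total == 0:
        raise SpectrumError("damage_frequency: zero surveyed GC sites")
    n_tsii = sum(1 for ev in events if (ev.ref_base, ev.obs_base) in TS_II)
    return n_tsii / gc_total


# ---------------------------------------------------------------------------
# endogenous vs contaminant contrast
# ---------------------------------------------------------------------------

@dataclass
class DamageComparison:
    chi2_statistic: float
    df: int
    p_value: float
    table: np.ndarray
    warnings: list[str] = field(default_factory=list)


def compare_damage(endo: tuple[Iterable[SubstitutionEvent], Sequence[AlignedSequence]],
                   contam: tuple[Iterable[SubstitutionEvent], Sequence[AlignedSequence]],
                   yates: bool = False) -> DamageComparison:
    """Pearson chi-square contrast of type-II damage between classes.

    The 2x2 table crosses class (endogenous/contaminant) with GC sites
    carrying vs not carrying a type-II event, per sequence and without
    deduplication; df = 1, upper-tail p.  Continuity correction is off by
    default (``yates=True`` enables it).
    """
    def _row(pair):
        events, aligned = pair
        if not aligned:
            raise SpectrumError("compare_damage: a class has no sequences")
        gc = sum(a.surveyed_site_counts()[1] for a in aligned)
        dam = sum(1 for ev in events if (ev.ref_base, ev.obs_base) in TS_II)
        return dam, gc - dam

    e_dam, e_ok = _row(endo)
    c_dam, c_ok = _row(contam)
    table = np.array([[e_dam, e_ok], [c_dam, c_ok]], dtype=float)
    warnings = []
    if e_dam + c_dam == 0:
        warnings.append("no type-II events in either class; p set to 1")
        return DamageComparison(chi2_statistic=0.0, df=1, p_value=1.0,
                                table=table, warnings=warnings)
    if min(table.sum(axis=0)) == 0 or min(table.sum(axis=1)) == 0:
        warnings.append("degenerate margin in 2x2 table")
        return DamageComparison(chi2_statistic=0.0, df=1, p_value=1.0,
                                table=table, warnings=warnings)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return DamageComparison(chi2_statistic=float(chi2), df=int(df),
                            p_value=float(p), table=table, warnings=warnings)


# ---------------------------------------------------------------------------
# estimators on deep tallies
# ---------------------------------------------------------------------------

def sequencing_error_rate(tally, locus: LocusSpec) -> float:
    """Estimate the per-site sequencing substitution rate from A/T reference
    rows of a deep tally (A/T sites are immune to deamination, so any
    non-reference base there is a sequencing error)."""
    n_err = n_obs = 0
    for _, row in tally.df.iterrows():
        if row["ref"] not in "AT":
            continue
        obs = {b: int(row[f"{b}_tot"]) for b in "ACGT"}
        called = sum(obs.values())
        n_obs += called
        n_err += called - obs[row["ref"]]
    if n_obs == 0:
        raise SpectrumError("no A/T reference rows in tally")
    return n_err / n_obs


def tally_typeII_frequency(tally, locus: LocusSpec) -> float:
    """Per-site-per-read type-II frequency straight from a deep tally:
    (T at C rows + A at G rows) over called bases at G/C rows."""
    n_tsii = n_obs = 0
    for _, row in tally.df.iterrows():
        if row["ref"] == "C":
            n_tsii += int(row["T_tot"])
        elif row["ref"] == "G":
            n_tsii += int(row["A_tot"])
        else:
            continue
        n_obs += sum(int(row[f"{b}_tot"]) for b in "ACGT")
    if n_obs == 0:
        raise SpectrumError("no G/C reference rows in tally")
    return n_tsii / n_obs


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------

def write_spectrum_table(spectra: Sequence[MisincorporationSpectrum],
                         path: str | Path,
                         damage_freq: float | None = None) -> None:
    """Write per-amplicon spectrum rows plus a pooled row (12 substitution
    types, %P shares, and optionally the damage frequency)."""
    rows = []
    listed = list(spectra)
    if len(listed) > 1:
        listed.append(pool_spectra(listed))
    for s in listed:
        row = {"label": s.label or "spectrum"}
        for r, o in SUB_TYPES:
            row[f"{r}>{o}"] = s.counts[(r, o)]
        row.update({
            "surveyed_AT": s.surveyed_at, "surveyed_GC": s.surveyed_gc,
            "surveyed_total": s.surveyed_total,
            "pct_TsI": f"{s.pct_tsi:.2f}", "pct_TsII": f"{s.pct_tsii:.2f}",
            "pct_Tv": f"{s.pct_tv:.2f}",
        })
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        if damage_freq is not None:
            fh.write(f"# damage_frequency_per_site_per_sequence\t{damage_freq:.6f}\n")
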