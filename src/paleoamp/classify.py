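"""Endogenous-vs-contaminant classification, per-PCR summaries, allele
fractions from deep tallies, investigator-profile matching and genotype
calling at a target variant.

Classification is deliberately conservative: a sequence is called endogenous
(or contaminant) only when a strict majority of the diagnostic sites it
covers carry that class's allele; ties, zero coverage, or a third allele at
any covered site leave it unclassified, so that damage-altered diagnostic
sites cannot silently flip a sequence's class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignedSequence
from .loci import DiagnosticSite, InvestigatorProfile, LocusSpec, PositionTally


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# per-sequence classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifiedSequence:
    query_id: str
    label: str  # endogenous | contaminant | unclassified
    sites_covered: int
    sites_matching_endogenous: int
    sites_matching_contaminant: int


def classify_haplotype(aln: AlignedSequence,
                       sites: Sequence[DiagnosticSite]) -> ClassifiedSequence:
    """Classify one aligned sequence at its haplogroup-diagnostic sites.

    Only sites with role ``haplogroup_diagnostic`` lying in the amplicon's
    unmasked interior are used; there must be at least one, else the locus
    configuration is broken for this amplicon.
    """
    interior = set(aln.locus.interior_positions(aln.amplicon))
    usable = [s for s in sites
              if s.role == "haplogroup_diagnostic" and s.position in interior]
    if not usable:
        raise ConfigurationError(
            f"no haplogroup-diagnostic site inside amplicon "
            f"{aln.amplicon.locus}:{aln.amplicon.pcr_id}")
    covered = n_endo = n_cont = 0
    third_allele = False
    for site in usable:
        base = aln.base_at(site.position)
        if base is None or base not in "ACGT":
            continue
        covered += 1
        if base == site.endogenous_allele:
            n_endo += 1
        elif base == site.contaminant_allele:
            n_cont += 1
        else:
            third_allele = True
    if third_allele or covered == 0 or n_endo == n_cont:
        label = "unclassified"
    elif n_endo > covered / 2:
        label = "endogenous"
    elif n_cont > covered / 2:
        label = "contaminant"
    else:
        label = "unclassified"
    return ClassifiedSequence(query_id=aln.query_id, label=label,
                              sites_covered=covered,
                              sites_matching_endogenous=n_endo,
                              sites_matching_contaminant=n_cont)


# ---------------------------------------------------------------------------
# per-PCR summaries and locus means
# ---------------------------------------------------------------------------

@dataclass
class AmpliconSummary:
    """Clone counts for one amplification, with the percent endogenous."""

    locus: str
    pcr_id: str
    n_endogenous: int
    n_contaminant: int
    n_unclassified: int = 0

    @property
    def pct_endogenous(self) -> float | None:
        denom = self.n_endogenous + self.n_contaminant
        if denom == 0:
            return None
        return 100.0 * self.n_endogenous / denom

    @property
    def n_total(self) -> int:
        return self.n_endogenous + self.n_contaminant + self.n_unclassified


def summarize_amplicon(classified: Iterable[ClassifiedSequence],
                       locus: str, pcr_id: str) -> AmpliconSummary:
    classified = list(classified)
    if not classified:
        raise ValueError("summarize_amplicon: empty input")
    counts = {"endogenous": 0, "contaminant": 0, "unclassified": 0}
    for c in classified:
        counts[c.label] += 1
    return AmpliconSummary(locus=locus, pcr_id=pcr_id,
                           n_endogenous=counts["endogenous"],
                           n_contaminant=counts["contaminant"],
                           n_unclassified=counts["unclassified"])


def locus_mean_pct(summaries: Sequence[AmpliconSummary]) -> float:
    """Unweighted mean of per-amplification percent-endogenous values.

    Amplifications whose percentage is undefined (no classified sequences)
    are excluded; averaging percentages rather than pooling clones gives
    every successful amplification equal weight.
    """
    pcts = [s.pct_endogenous for s in summaries if s.pct_endogenous is not None]
    if not pcts:
        raise ValueError("locus_mean_pct: no summary with a defined percentage")
    return sum(pcts) / len(pcts)


# ---------------------------------------------------------------------------
# deep-tally allele fractions
# ---------------------------------------------------------------------------

def tally_allele_fractions(tally: PositionTally, site: DiagnosticSite,
                           ) -> tuple[float, float, float, int]:
    """(ancestral_pct, derived_pct, other_pct, total_reads) at a target site.

    Percentages are over the total read count at the site's tally row (gaps
    count toward 'other').  For a haplogroup-diagnostic site the endogenous
    allele plays the ancestral role and the contaminant allele the derived.
    """
    anc = site.ancestral_allele or site.endogenous_allele
    der = site.derived_allele or site.contaminant_allele
    counts = tally.counts(site.position)
    total = int(tally.row(site.position)["total"])
    if total == 0:
        raise ValueError(f"no reads at gene_pos {site.position}")
    anc_pct = 100.0 * counts[anc] / total
    der_pct = 100.0 * counts[der] / total
    return anc_pct, der_pct, 100.0 - anc_pct - der_pct, total


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

@dataclass
class PcrAlleleCounts:
    """Ancestral/derived molecule counts from one independent amplification."""

    pcr_id: str
    n_ancestral: int
    n_derived: int
    platform: str = "clones"  # "clones" or "reads"


@dataclass
class GenotypeCall:
    site: DiagnosticSite
    call: str  # homozygous_ancestral | homozygous_derived | heterozygous | undetermined
    derived_fraction_clones: float | None
    derived_fraction_reads: float | None
    n_independent_pcrs_with_derived: int
    damage_consistent_derived: bool
    warnings: list[str] = field(default_factory=list)


def is_damage_consistent(site: DiagnosticSite) -> bool:
    """True iff the ancestral-to-derived change is C->T or G->A, i.e. a
    type-II transition that post-mortem cytosine deamination can mimic."""
    anc = site.ancestral_allele or site.endogenous_allele
    der = site.derived_allele or site.contaminant_allele
    return (anc, der) in {("C", "T"), ("G", "A")}


def call_genotype(counts: Sequence[PcrAlleleCounts], site: DiagnosticSite,
                  min_pcrs: int = 2, derived_threshold: float = 0.10,
                  ) -> GenotypeCall:
    """Call the genotype at a target variant from replicated amplifications.

    An allele is accepted as genuine only if it was observed in at least
    ``min_pcrs`` independent amplifications AND its pooled fraction over all
    molecules (clones plus reads) reaches ``derived_threshold``; this is the
    standard ancient-DNA replication criterion, and keeps sporadic
    contamination or damage (e.g. a sub-2% derived read fraction) from
    producing a heterozygous call.  Both alleles genuine -> heterozygous;
    exactly one -> homozygous for it; neither -> undetermined.
    """
    if not counts:
        return GenotypeCall(site=site, call="undetermined",
                            derived_fraction_clones=None,
                            derived_fraction_reads=None,
                            n_independent_pcrs_with_derived=0,
                            damage_consistent_derived=is_damage_consistent(site),
                            warnings=["no data"])
    tot_anc = sum(c.n_ancestral for c in counts)
    tot_der = sum(c.n_derived for c in counts)
    pooled = tot_anc + tot_der
    warnings: list[str] = []
    if pooled == 0:
        return GenotypeCall(site=site, call="undetermined",
                            derived_fraction_clones=None,
                            derived_fraction_reads=None,
                            n_independent_pcrs_with_derived=0,
                            damage_consistent_derived=is_damage_consistent(site),
                            warnings=["no classified molecules"])

    def _fraction(platform: str) -> float | None:
        sub = [c for c in counts if c.platform == platform]
        denom = sum(c.n_ancestral + c.n_derived for c in sub)
        if denom == 0:
            return None
        return sum(c.n_derived for c in sub) / denom

    def _genuine(allele_total: int, n_pcrs_with: int) -> tuple[bool, str | None]:
        frac = allele_total / pooled
        replicated = n_pcrs_with >= min_pcrs
        abundant = frac >= derived_threshold
        if replicated and abundant:
            return True, None
        if allele_total > 0 and abundant and not replicated:
            return False, (f"allele at pooled fraction {frac:.2f} but seen in only "
                           f"{n_pcrs_with} PCR(s) (< {min_pcrs})")
        if allele_total > 0 and replicated and not abundant:
            return False, (f"allele replicated in {n_pcrs_with} PCRs but pooled "
                           f"fraction {frac:.4f} < {derived_threshold}")
        return False, None

    pcrs_with_der = sum(1 for c in counts if c.n_derived > 0)
    pcrs_with_anc = sum(1 for c in counts if c.n_ancestral > 0)
    der_ok, w1 = _genuine(tot_der, pcrs_with_der)
    anc_ok, w2 = _genuine(tot_anc, pcrs_with_anc)
    for w, tag in ((w1, "derived"), (w2, "ancestral")):
        if w:
            warnings.append(f"{tag}: {w}")
    if anc_ok and der_ok:
        call = "heterozygous"
    elif anc_ok:
        call = "homozygous_ancestral"
    elif der_ok:
        call = "homozygous_derived"
    else:
        call = "undetermined"
    return GenotypeCall(site=site, call=call,
                        derived_fraction_clones=_fraction("clones"),
                        derived_fraction_reads=_fraction("reads"),
                        n_independent_pcrs_with_derived=pcrs_with_der,
                        damage_consistent_derived=is_damage_consistent(site),
                        warnings=warnings)


# ---------------------------------------------------------------------------
# investigator-profile matching
# ---------------------------------------------------------------------------

def match_contaminant_profile(contaminant_motif: Iterable[tuple[int, str]],
                              profiles: Sequence[InvestigatorProfile],
                              ) -> list[tuple[str, int, bool]]:
    """Rank investigator profiles by mismatches to a contaminant motif.

    Both motifs list differences from the same reference haplotype; the
    comparison runs over the union of positions named by either motif, a
    position present in only one of the two counting as a mismatch.  Returns
    ``(person_id, n_mismatches, exact)`` sorted by mismatch count (ties keep
    their input order); ``exact`` flags a perfect (0-mismatch) match.
    """
    if not profiles:
        raise ValueError("no profiles to match against")
    motif = dict(contaminant_motif)
    results: list[tuple[str, int, bool]] = []
    any_positions = False
    for prof in profiles:
        theirs = dict(prof.mt_motif)
        union = set(motif) | set(theirs)
        if union:
            any_positions = True
        mism = sum(1 for p in union if motif.get(p) != theirs.get(p))
        results.append((prof.person_id, mism, mism == 0))
    if not any_positions:
        raise ValueError("no positions to compare: contaminant motif and all "
                         "profile motifs are empty")
    results.sort(key=lambda r: r[1])
    return results


def motif_from_consensus(consensus: str, start_pos: int, locus: LocusSpec,
                         ) -> list[tuple[int, str]]:
    """Differences of an ungapped consensus from the locus reference, as a
    (position, base) motif; ambiguous consensus bases are skipped."""
    motif = []
    idx = locus.to_index(start_pos)
    for offset, base in enumerate(consensus):
        ref = locus.reference[idx - 1 + offset]
        if base in "ACGT" and base != ref:
            motif.append((locus.to_coord(idx + offset), base))
    return motif


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def write_classification_table(summaries: Sequence[AmpliconSummary],
                               path: str | Path,
                               mean_pct: float | None = None) -> None:
    """Write a per-amplification classification TSV with an optional mean row."""
    rows = []
    for s in summaries:
        pct = s.pct_endogenous
        rows.append({"locus": s.locus, "pcr_id": s.pcr_id,
                     "n_endogenous": s.n_endogenous,
                     "n_contaminant": s.n_contaminant,
                     "n_unclassified": s.n_unclassified,
                     "pct_endogenous": "NA" if pct is None else f"{pct:.2f}"})
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        if mean_pct is not None and not math.isnan(mean_pct):
            fh.write(f"# mean_pct_endogenous\t{mean_pct:.2f}\n")


def write_genotype_table(calls: Sequence[GenotypeCall], path: str | Path) -> None:
    rows = []
    for g in calls:
        rows.append({
            "position": g.site.position,
            "call": g.call,
            "derived_fraction_clones": ("NA" if g.derived_fraction_clones is None
                                        else f"{g.derived_fraction_clones:.4f}"),
            "derived_fraction_reads": ("NA" if g.derived_fraction_reads is None
                                       else f"{g.derived_fraction_reads:.4f}"),
            "n_pcrs_with_derived": g.n_independent_pcrs_with_derived,
            "damage_consistent_derived": g.damage_consistent_derived,
            "warnings": "; ".join(g.warnings) or ".",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_allele_fraction_table(rows: Sequence[dict], path: str | Path) -> None:
    """Write the deep-sequencing allele-fraction TSV (one row per target site)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
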