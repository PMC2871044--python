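"""Simulator for damaged, contaminated amplicon sequencing experiments.

The generative model mirrors the assumed data-generating process of a
cloned-amplicon ancient-DNA experiment:

* each PCR starts from a handful of template molecules, each of which is a
  modern contaminant with probability ``c`` and otherwise an endogenous
  molecule carrying fresh post-mortem deamination damage (each C->T and each
  G->A independently with probability ``delta/2``);
* clones copy a uniformly chosen template and add per-site polymerase error
  ``epsilon`` — clones of one template therefore share its damage events,
  which is exactly the within-amplicon correlation that per-amplicon event
  deduplication removes;
* deep-sequencing reads are drawn one template molecule per read (emulsion
  PCR isolates single molecules) with per-site sequencing error ``eta``;
* whole PCRs fail with probability ``p_dropout``.

Every run is reproducible from its seed, and a truth table records each
simulated sequence's class and injected events for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .loci import Amplicon, LocusSpec, PositionTally, write_fasta

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults reflect a typical well-preserved-specimen cloning experiment:
    ~12% modern contamination, 2% per-GC-site template deamination, 1e-3
    polymerase and 5e-4 sequencing substitution error, 20 clones from each of
    3 PCRs seeded by 2 template molecules, a quarter of PCRs failing, and a
    ~45k-read deep-sequencing run.
    """

    locus: LocusSpec
    seed: int
    endogenous_haplotype: str | None = None
    contaminant_haplotype: str | None = None
    c: float = 0.12
    delta: float = 0.02
    epsilon: float = 0.001
    eta: float = 0.0005
    templates_per_pcr: int = 2
    clones_per_pcr: int = 20
    n_pcrs: int = 3
    n_reads: int = 45120
    p_dropout: float = 0.25

    def __post_init__(self) -> None:
        for name in ("c", "delta", "epsilon", "eta", "p_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.templates_per_pcr < 1:
            raise ValueError("templates_per_pcr must be >= 1")
        if self.endogenous_haplotype is None:
            self.endogenous_haplotype = self.locus.reference
        if self.contaminant_haplotype is None:
            self.contaminant_haplotype = contaminant_haplotype(self.locus)
        for name in ("endogenous_haplotype", "contaminant_haplotype"):
            if len(getattr(self, name)) != len(self.locus.reference):
                raise ValueError(f"{name} length differs from reference")


def contaminant_haplotype(locus: LocusSpec) -> str:
    """Reference haplotype with the contaminant allele at every diagnostic site."""
    seq = list(locus.reference)
    for site in locus.diagnostic_sites:
        seq[locus.to_index(site.position) - 1] = site.contaminant_allele
    return "".join(seq)


@dataclass
class SimRecord:
    """Ground truth for one simulated sequence."""

    query_id: str
    source_class: str          # endogenous | contaminant
    template_id: str
    damage_events: tuple[tuple[int, str, str], ...] = ()  # (gene_pos, ref, obs)
    error_events: tuple[tuple[int, str, str], ...] = ()


@dataclass
class CloneExperiment:
    locus: LocusSpec
    #: amplification instance id -> per-instance Amplicon (pcr_id carries the replicate)
    amplicons: dict[str, Amplicon] = field(default_factory=dict)
    #: amplification instance id -> [(clone_id, sequence), ...]
    clones: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    truth: list[SimRecord] = field(default_factory=list)
    dropped_pcrs: list[str] = field(default_factory=list)


@dataclass
class ReadTruth:
    n_reads: int
    n_contaminant: int
    n_damage_events: int
    n_error_events: int
    read_class: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# template damage
# ---------------------------------------------------------------------------

def damage_template(template: str, delta: float, rng: np.random.Generator,
                    ) -> tuple[str, list[tuple[int, str, str]]]:
    """Apply deamination damage to one template molecule.

    Each C flips to T and each G to A, independently, with probability
    ``delta/2``.  Returns the damaged string and the exact event list as
    (1-based index, ref base, observed base).
    """
    arr = np.frombuffer(template.encode(), dtype="S1").copy()
    u = rng.random(len(arr))
    hit_c = (arr == b"C") & (u < delta / 2)
    hit_g = (arr == b"G") & (u < delta / 2)
    events = [(int(i) + 1, "C", "T") for i in np.flatnonzero(hit_c)]
    events += [(int(i) + 1, "G", "A") for i in np.flatnonzero(hit_g)]
    arr[hit_c] = b"T"
    arr[hit_g] = b"A"
    events.sort()
    return arr.tobytes().decode(), events


def _point_errors(seq: str, rate: float, rng: np.random.Generator,
                  ) -> tuple[str, list[tuple[int, str, str]]]:
    """Uniform substitution errors: each site hit with ``rate``, the new base
    drawn uniformly from the three alternatives."""
    if rate == 0.0:
        return seq, []
    arr = np.array([_BASE_INDEX[b] for b in seq], dtype=np.int8)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hits) == 0:
        return seq, []
    shift = rng.integers(1, 4, size=len(hits))
    events = []
    for i, s in zip(hits, shift):
        old = _BASES[arr[i]]
        arr[i] = (arr[i] + s) % 4
        events.append((int(i) + 1, str(old), str(_BASES[arr[i]])))
    return "".join(_BASES[arr]), events


# ---------------------------------------------------------------------------
# cloned-amplicon experiment
# ---------------------------------------------------------------------------

def simulate_clone_experiment(config: SimConfig) -> CloneExperiment:
    """Simulate replicated PCRs, cloning and Sanger sequencing for one locus.

    For each amplicon design, ``n_pcrs`` independent amplifications are
    attempted (instance ids ``<design>.<replicate>``); surviving ones draw
    ``templates_per_pcr`` template molecules and ``clones_per_pcr`` clones.
    """
    rng = np.random.default_rng(config.seed)
    locus = config.locus
    exp = CloneExperiment(locus=locus)
    for design in locus.amplicons:
        span_i = locus.to_index(design.span[0])
        span_j = locus.to_index(design.span[1])
        int_i = locus.to_index(design.primer_f_span[1]) + 1
        int_j = locus.to_index(design.primer_r_span[0]) - 1
        endo_full = config.endogenous_haplotype[span_i - 1:span_j]
        cont_full = config.contaminant_haplotype[span_i - 1:span_j]
        for r in range(1, config.n_pcrs + 1):
            amp_id = f"{design.pcr_id}.{r}"
            if rng.random() < config.p_dropout:
                exp.dropped_pcrs.append(f"{locus.name}:{amp_id}")
                continue
            inst = dataclasses.replace(design, pcr_id=amp_id)
            exp.amplicons[amp_id] = inst
            templates: list[tuple[str, str, tuple, str]] = []
            for t in range(config.templates_per_pcr):
                tid = f"{locus.name}:{amp_id}:t{t + 1}"
                if rng.random() < config.c:
                    templates.append(("contaminant", cont_full, (), tid))
                else:
                    interior = config.endogenous_haplotype[int_i - 1:int_j]
                    damaged, ev = damage_template(interior, config.delta, rng)
                    full = (endo_full[: int_i - span_i] + damaged
                            + endo_full[int_j - span_i + 1:])
                    pub = tuple((locus.to_coord(int_i + i - 1), rb, ob)
                                for i, rb, ob in ev)
                    templates.append(("endogenous", full, pub, tid))
            clone_list = []
            for j in range(1, config.clones_per_pcr + 1):
                cls, tmpl_seq, dmg, tid = templates[int(rng.integers(len(templates)))]
                clone_seq, err = _point_errors(tmpl_seq, config.epsilon, rng)
                err_pub = tuple((locus.to_coord(span_i + i - 1), rb, ob)
                                for i, rb, ob in err)
                cid = f"{locus.name}:{amp_id}:c{j}"
                clone_list.append((cid, clone_seq))
                exp.truth.append(SimRecord(query_id=cid, source_class=cls,
                                           template_id=tid, damage_events=dmg,
                                           error_events=err_pub))
            exp.clones[amp_id] = clone_list
    return exp


# ---------------------------------------------------------------------------
# deep-sequencing reads and tallies
# ---------------------------------------------------------------------------

def simulate_reads(config: SimConfig, amplicon: Amplicon,
                   ) -> tuple[list[str], ReadTruth]:
    """Simulate primer-trimmed deep-sequencing reads over one amplicon's
    unmasked interior, one fresh template molecule per read."""
    rng = np.random.default_rng(config.seed)
    locus = config.locus
    positions = locus.interior_positions(amplicon)
    i0 = locus.to_index(positions[0])
    i1 = locus.to_index(positions[-1])
    endo = np.array([_BASE_INDEX[b]
                     for b in config.endogenous_haplotype[i0 - 1:i1]], dtype=np.int8)
    cont = np.array([_BASE_INDEX[b]
                     for b in config.contaminant_haplotype[i0 - 1:i1]], dtype=np.int8)
    n, length = config.n_reads, len(endo)
    is_cont = rng.random(n) < config.c
    mat = np.where(is_cont[:, None], cont[None, :], endo[None, :]).astype(np.int8)

    # deamination on endogenous molecules only (fresh template per read)
    u = rng.random((n, length))
    c_idx, t_idx, g_idx, a_idx = (_BASE_INDEX[b] for b in "CTGA")
    dmg = (~is_cont[:, None]) & (u < config.delta / 2) & (
        (mat == c_idx) | (mat == g_idx))
    mat[dmg & (mat == c_idx)] = t_idx
    n_dmg = int(dmg.sum())
    dmg_g = dmg & (mat == g_idx)
    mat[dmg_g] = a_idx

    err = rng.random((n, length)) < config.eta
    n_err = int(err.sum())
    if n_err:
        shift = rng.integers(1, 4, size=(n, length), dtype=np.int8)
        mat[err] = (mat[err] + shift[err]) % 4

    reads = ["".join(_BASES[row]) for row in mat]
    truth = ReadTruth(n_reads=n, n_contaminant=int(is_cont.sum()),
                      n_damage_events=n_dmg, n_error_events=n_err,
                      read_class=is_cont)
    return reads, truth


def simulate_read_tally(config: SimConfig, amplicon: Amplicon,
                        ) -> tuple[PositionTally, ReadTruth]:
    """Simulate a deep run and tabulate it into a per-position tally
    (primer regions excluded, matching the tally-table convention)."""
    reads, truth = simulate_reads(config, amplicon)
    locus = config.locus
    positions = locus.interior_positions(amplicon)
    mat = np.array([[_BASE_INDEX[b] for b in read] for read in reads],
                   dtype=np.int8)
    rows = []
    for k, pos in enumerate(positions):
        col = mat[:, k]
        counts = [int((col == _BASE_INDEX[b]).sum()) for b in "ACGT"]
        rows.append((k + 1, pos, locus.ref_base(pos), *counts, 0))
    tally = PositionTally.from_rows(locus.name, rows).validate(locus)
    return tally, truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_experiment(exp: CloneExperiment, outdir: str | Path,
                     tally: PositionTally | None = None,
                     tally_amplicon: str | None = None) -> dict:
    """Write clone FASTAs (one per amplification), the truth table, and an
    analysis manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"locus": exp.locus.name, "amplifications": [], "tallies": []}
    for amp_id, clones in sorted(exp.clones.items()):
        fname = f"{exp.locus.name}_{amp_id}.fasta"
        write_fasta(clones, outdir / fname)
        design = amp_id.rsplit(".", 1)[0]
        manifest["amplifications"].append(
            {"amp_id": amp_id, "design": design, "fasta": fname})
    rows = [{
        "query_id": rec.query_id, "source_class": rec.source_class,
        "template_id": rec.template_id,
        "damage_events": ";".join(f"{p}{r}>{o}" for p, r, o in rec.damage_events) or ".",
        "error_events": ";".join(f"{p}{r}>{o}" for p, r, o in rec.error_events) or ".",
    } for rec in exp.truth]
    pd.DataFrame(rows).to_csv(outdir / f"{exp.locus.name}_truth.tsv",
                              sep="\t", index=False, lineterminator="\n")
    if tally is not None:
        from .loci import write_tally_table
        fname = f"{exp.locus.name}_tally.tsv"
        write_tally_table(tally, outdir / fname)
        manifest["tallies"].append({"amp_id": tally_amplicon or "454",
                                    "design": (tally_amplicon or "454").rsplit(".", 1)[0],
                                    "tsv": fname})
    return manifest
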