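"""Locus registry and file formats for amplicon-resequencing experiments.

A :class:`LocusSpec` describes one amplified region: its reference sequence,
the published coordinate system (1-based, possibly negative with no position
zero, as for the lactase-promoter position -13910), the amplicons with their
primer spans (masked from every statistic), and the diagnostic sites that
separate the endogenous individual from modern contaminants.

This module also reads and writes every external format the pipeline touches:
FASTA (references, clones, reads, consensus), the per-position base-count
tally TSV produced by deep amplicon sequencing, the investigator-profile TSV
used for contamination tracing, and the YAML locus-configuration dialect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_BASES = frozenset("ACGT")
IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN-")

#: IUPAC ambiguity code for each non-empty set of bases.
IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

TALLY_COLUMNS = ["amplicon_pos", "gene_pos", "ref",
                 "A_tot", "C_tot", "G_tot", "T_tot", "gap_tot", "total"]


class LocusConfigError(ValueError):
    """A locus definition violates its invariants."""


class FormatError(ValueError):
    """An external file does not conform to its documented dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Amplicon:
    """One PCR design on a locus: full span plus the two primer spans.

    All coordinates are published (1-based inclusive) coordinates.  Primer
    spans sit at the two ends of ``span`` and are masked from every
    downstream statistic.
    """

    locus: str
    pcr_id: str
    span: tuple[int, int]
    primer_f_span: tuple[int, int]
    primer_r_span: tuple[int, int]


@dataclass(frozen=True)
class DiagnosticSite:
    """A site whose allele separates endogenous from contaminant molecules.

    ``role`` is ``haplogroup_diagnostic`` for motif/authentication sites and
    ``target_variant`` for the variant being genotyped, in which case
    ``ancestral_allele``/``derived_allele`` are also set (for the loci modelled
    here the endogenous allele is the ancestral one).
    """

    position: int
    endogenous_allele: str
    contaminant_allele: str
    role: str = "haplogroup_diagnostic"
    ancestral_allele: str | None = None
    derived_allele: str | None = None

    def __post_init__(self) -> None:
        for name in ("endogenous_allele", "contaminant_allele"):
            b = getattr(self, name)
            if b not in DNA_BASES:
                raise LocusConfigError(
                    f"site {self.position}: {name} {b!r} is not a single ACGT base")
        if self.endogenous_allele == self.contaminant_allele:
            raise LocusConfigError(
                f"site {self.position}: endogenous and contaminant alleles are equal")
        if self.role not in ("haplogroup_diagnostic", "target_variant"):
            raise LocusConfigError(f"site {self.position}: unknown role {self.role!r}")
        if self.role == "target_variant":
            if self.ancestral_allele not in DNA_BASES or self.derived_allele not in DNA_BASES:
                raise LocusConfigError(
                    f"site {self.position}: target_variant requires ancestral/derived alleles")


@dataclass
class LocusSpec:
    """A named locus with its reference, coordinate system, amplicons and sites.

    ``coord_offset`` maps sequence index 1 to the published coordinate; for
    negative systems (``coord_offset < 0``) the published axis has no
    position 0, which the mapping skips.
    """

    name: str
    molecule: str
    coord_offset: int
    reference: str
    amplicons: list[Amplicon] = field(default_factory=list)
    diagnostic_sites: list[DiagnosticSite] = field(default_factory=list)

    # -- coordinate mapping -------------------------------------------------
    def to_coord(self, index: int) -> int:
        """Published coordinate of 1-based sequence ``index``."""
        if not 1 <= index <= len(self.reference):
            raise LocusConfigError(
                f"{self.name}: index {index} outside reference (1..{len(self.reference)})")
        c = self.coord_offset + index - 1
        if self.coord_offset < 0 and c >= 0:
            c += 1  # the published axis skips 0
        return c

    def to_index(self, position: int) -> int:
        """1-based sequence index of a published coordinate."""
        if position == 0 and self.coord_offset < 0:
            raise LocusConfigError(f"{self.name}: position 0 does not exist on this axis")
        raw = position
        if self.coord_offset < 0 and position > 0:
            raw = position - 1
        i = raw - self.coord_offset + 1
        if not 1 <= i <= len(self.reference):
            raise LocusConfigError(
                f"{self.name}: position {position} outside reference")
        return i

    def ref_base(self, position: int) -> str:
        return self.reference[self.to_index(position) - 1]

    def ref_slice(self, span: tuple[int, int]) -> str:
        i, j = self.to_index(span[0]), self.to_index(span[1])
        return self.reference[i - 1:j]

    def interior_positions(self, amplicon: Amplicon) -> list[int]:
        """Published coordinates of the unmasked interior of an amplicon."""
        i = self.to_index(amplicon.primer_f_span[1]) + 1
        j = self.to_index(amplicon.primer_r_span[0]) - 1
        return [self.to_coord(k) for k in range(i, j + 1)]

    def amplicon(self, pcr_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.pcr_id == pcr_id:
                return a
        raise KeyError(f"{self.name}: no amplicon {pcr_id!r}")

    # -- validation ---------------------------------------------------------
    def validate(self) -> "LocusSpec":
        if not self.reference:
            raise LocusConfigError(f"{self.name}: empty reference")
        if set(self.reference) - DNA_BASES:
            raise LocusConfigError(
                f"{self.name}: reference contains non-ACGT characters")
        seen = set()
        for amp in self.amplicons:
            if amp.pcr_id in seen:
                raise LocusConfigError(f"{self.name}: duplicate amplicon id {amp.pcr_id!r}")
            seen.add(amp.pcr_id)
            try:
                s0, s1 = (self.to_index(amp.span[0]), self.to_index(amp.span[1]))
                f0, f1 = (self.to_index(amp.primer_f_span[0]), self.to_index(amp.primer_f_span[1]))
                r0, r1 = (self.to_index(amp.primer_r_span[0]), self.to_index(amp.primer_r_span[1]))
            except LocusConfigError as exc:
                raise LocusConfigError(
                    f"{self.name}/{amp.pcr_id}: coordinate outside reference ({exc})") from exc
            if s0 > s1:
                raise LocusConfigError(f"{self.name}/{amp.pcr_id}: inverted span")
            if f0 != s0 or r1 != s1:
                raise LocusConfigError(
                    f"{self.name}/{amp.pcr_id}: primer spans must sit at the amplicon ends")
            if f1 >= r0:
                raise LocusConfigError(
                    f"{self.name}/{amp.pcr_id}: primer spans overlap")
            if r0 - f1 - 1 < 1:
                raise LocusConfigError(
                    f"{self.name}/{amp.pcr_id}: empty unmasked interior")
        for site in self.diagnostic_sites:
            idx = self.to_index(site.position)  # raises if outside reference
            inside = any(
                self.to_index(a.primer_f_span[1]) < idx < self.to_index(a.primer_r_span[0])
                for a in self.amplicons)
            if self.amplicons and not inside:
                raise LocusConfigError(
                    f"{self.name}: diagnostic site {site.position} not inside any "
                    f"amplicon's unmasked interior")
        return self

    def haplogroup_sites(self) -> list[DiagnosticSite]:
        return [s for s in self.diagnostic_sites if s.role == "haplogroup_diagnostic"]

    def target_sites(self) -> list[DiagnosticSite]:
        return [s for s in self.diagnostic_sites if s.role == "target_variant"]


@dataclass
class PositionTally:
    """Per-position A/C/G/T/gap read counts for one deep-sequenced amplicon.

    Backed by a DataFrame with columns ``amplicon_pos, gene_pos, ref, A_tot,
    C_tot, G_tot, T_tot, gap_tot, total`` (primer regions excluded).
    """

    locus: str
    df: pd.DataFrame

    def validate(self, locus: LocusSpec | None = None) -> "PositionTally":
        missing = [c for c in TALLY_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"tally missing columns {missing}")
        base_sum = self.df[["A_tot", "C_tot", "G_tot", "T_tot", "gap_tot"]].sum(axis=1)
        bad = self.df.loc[base_sum != self.df["total"], "gene_pos"]
        if len(bad):
            raise FormatError(
                f"tally: total != A+C+G+T+gap at gene_pos {bad.iloc[0]}")
        gp = self.df["gene_pos"].to_numpy()
        if not (gp[1:] > gp[:-1]).all():
            raise FormatError("tally: gene_pos not strictly increasing")
        if locus is not None:
            for _, row in self.df.iterrows():
                expect = locus.ref_base(int(row["gene_pos"]))
                if row["ref"] != expect:
                    raise FormatError(
                        f"tally: ref base {row['ref']!r} at gene_pos {row['gene_pos']} "
                        f"does not match locus reference {expect!r}")
        return self

    def row(self, gene_pos: int) -> pd.Series:
        hit = self.df[self.df["gene_pos"] == gene_pos]
        if hit.empty:
            raise KeyError(f"tally has no row at gene_pos {gene_pos}")
        return hit.iloc[0]

    def counts(self, gene_pos: int) -> dict[str, int]:
        r = self.row(gene_pos)
        return {"A": int(r["A_tot"]), "C": int(r["C_tot"]), "G": int(r["G_tot"]),
                "T": int(r["T_tot"]), "-": int(r["gap_tot"])}

    @classmethod
    def from_rows(cls, locus: str,
                  rows: Iterable[tuple[int, int, str, int, int, int, int, int]],
                  ) -> "PositionTally":
        """Build from (amplicon_pos, gene_pos, ref, A, C, G, T, gap) rows."""
        recs = []
        for amplicon_pos, gene_pos, ref, a, c, g, t, gap in rows:
            recs.append((amplicon_pos, gene_pos, ref, a, c, g, t, gap,
                         a + c + g + t + gap))
        df = pd.DataFrame.from_records(recs, columns=TALLY_COLUMNS)
        return cls(locus=locus, df=df).validate()


@dataclass(frozen=True)
class InvestigatorProfile:
    """Genetic profile of one person who handled the sample.

    ``mt_motif`` lists the positions at which the person's mitochondrial
    haplotype differs from the endogenous reference haplotype, with the base
    carried; ``nuclear_genotypes`` maps a site label (``"LCT:-13910"``) to the
    diploid genotype as an allele pair.
    """

    person_id: str
    mt_motif: tuple[tuple[int, str], ...] = ()
    nuclear_genotypes: dict[str, tuple[str, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, upper-cased sequence) pairs.

    Duplicate ids, empty sequences and non-IUPAC letters are rejected.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        if set(seq) - IUPAC_LETTERS:
            raise FormatError(f"{path}: non-IUPAC characters in {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# tally tables (deep-sequencing per-position counts)
# ---------------------------------------------------------------------------

def read_tally_table(path: str | Path, locus: LocusSpec | None = None) -> PositionTally:
    """Read a per-position count TSV (columns: amplicon_pos, gene_pos, ref,
    A_tot, C_tot, G_tot, T_tot, gap_tot, total)."""
    df = pd.read_csv(path, sep="\t")
    name = locus.name if locus is not None else Path(path).stem
    return PositionTally(locus=name, df=df).validate(locus)


def write_tally_table(tally: PositionTally, path: str | Path) -> None:
    tally.df.to_csv(path, sep="\t", index=False, lineterminator="\n",
                    columns=TALLY_COLUMNS)


# ---------------------------------------------------------------------------
# investigator profiles
# ---------------------------------------------------------------------------

def _parse_motif(text: str) -> tuple[tuple[int, str], ...]:
    out = []
    text = text.strip()
    if not text or text == ".":
        return ()
    for token in text.split(","):
        token = token.strip()
        pos, base = int(token[:-1]), token[-1].upper()
        if base not in DNA_BASES:
            raise FormatError(f"motif token {token!r}: base must be ACGT")
        out.append((pos, base))
    return tuple(out)


def _parse_genotypes(text: str) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    text = text.strip()
    if not text or text == ".":
        return out
    for token in text.split(";"):
        label, geno = token.strip().rsplit("=", 1)
        a, b = geno.split("/")
        out[label] = (a.upper(), b.upper())
    return out


def read_profile_table(path: str | Path) -> list[InvestigatorProfile]:
    """Read the investigator-profile TSV (person_id, mt_motif, nuclear_genotypes)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(InvestigatorProfile(
            person_id=row["person_id"],
            mt_motif=_parse_motif(row.get("mt_motif", "")),
            nuclear_genotypes=_parse_genotypes(row.get("nuclear_genotypes", "")),
        ))
    if not profiles:
        raise FormatError(f"{path}: no profiles")
    return profiles


# ---------------------------------------------------------------------------
# locus configuration
# ---------------------------------------------------------------------------

def load_locus_config(path: str | Path) -> list[LocusSpec]:
    """Load and validate a YAML locus registry.

    Each locus entry gives ``name``, ``molecule``, ``coord_offset``, either an
    inline ``reference`` string or ``reference_fasta``/``reference_id``
    (resolved relative to the config file), ``amplicons`` and
    ``diagnostic_sites``.  Every :class:`LocusSpec` invariant is checked.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "loci" not in doc:
        raise LocusConfigError(f"{path}: expected a top-level 'loci' list")
    fasta_cache: dict[str, dict[str, str]] = {}
    loci = []
    for entry in doc["loci"]:
        name = entry["name"]
        if "reference" in entry:
            ref = str(entry["reference"]).upper()
        else:
            fasta = str(path.parent / entry["reference_fasta"])
            if fasta not in fasta_cache:
                fasta_cache[fasta] = dict(read_fasta(fasta))
            rid = entry.get("reference_id", name)
            if rid not in fasta_cache[fasta]:
                raise LocusConfigError(f"{name}: record {rid!r} not in {fasta}")
            ref = fasta_cache[fasta][rid]
        amplicons = [
            Amplicon(locus=name, pcr_id=str(a["pcr_id"]),
                     span=tuple(a["span"]),
                     primer_f_span=tuple(a["primer_f"]),
                     primer_r_span=tuple(a["primer_r"]))
            for a in entry.get("amplicons", [])
        ]
        sites = [
            DiagnosticSite(position=int(s["position"]),
                           endogenous_allele=str(s["endogenous"]).upper(),
                           contaminant_allele=str(s["contaminant"]).upper(),
                           role=s.get("role", "haplogroup_diagnostic"),
                           ancestral_allele=(str(s["ancestral"]).upper()
                                             if "ancestral" in s else None),
                           derived_allele=(str(s["derived"]).upper()
                                           if "derived" in s else None))
            for s in entry.get("diagnostic_sites", [])
        ]
        loci.append(LocusSpec(name=name, molecule=entry["molecule"],
                              coord_offset=int(entry["coord_offset"]),
                              reference=ref, amplicons=amplicons,
                              diagnostic_sites=sites).validate())
    return loci


def write_locus_config(loci: Sequence[LocusSpec], path: str | Path) -> None:
    """Write a registry back out (references inline) in the YAML dialect."""
    doc = {"loci": []}
    for locus in loci:
        doc["loci"].append({
            "name": locus.name,
            "molecule": locus.molecule,
            "coord_offset": locus.coord_offset,
            "reference": locus.reference,
            "amplicons": [
                {"pcr_id": a.pcr_id, "span": list(a.span),
                 "primer_f": list(a.primer_f_span), "primer_r": list(a.primer_r_span)}
                for a in locus.amplicons],
            "diagnostic_sites": [
                {k: v for k, v in {
                    "position": s.position, "role": s.role,
                    "endogenous": s.endogenous_allele,
                    "contaminant": s.contaminant_allele,
                    "ancestral": s.ancestral_allele,
                    "derived": s.derived_allele}.items() if v is not None}
                for s in locus.diagnostic_sites],
        })
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def bundled_loci() -> list[LocusSpec]:
    """The bundled synthetic locus registry (published amplicon geometry on
    synthetic reference backbones)."""
    from importlib.resources import files
    return load_locus_config(files("paleoamp").joinpath("data/synthetic_loci.yaml"))


def bundled_path(name: str) -> Path:
    from importlib.resources import files
    return Path(str(files("paleoamp").joinpath(f"data/{name}")))
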