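"""Global pairwise alignment of clones/reads to their amplicon reference.

Each clone (Sanger) or read (pyrosequencing) is aligned globally to the
reference slice of the amplicon that produced it; primer columns are masked,
and mismatches/indels are extracted as events in published coordinates.  The
reference frame acts as the common frame for all sequences of one amplicon
(star alignment) — no multiple alignment is ever computed.

Scoring is fixed for determinism: match +1, mismatch -1, gap open -3 for the
first gapped column and -1 for each additional column of the same gap run.
The optimal alignment is computed by Biopython's affine-gap global aligner;
ties between co-optimal paths resolve to the aligner's first reported path,
which is deterministic for fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .loci import DNA_BASES, Amplicon, LocusSpec

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -3.0   # score of the first column of a gap run
GAP_EXTEND = -1.0  # score of each subsequent column


class AlignmentInputError(ValueError):
    """Query grossly mismatched to the amplicon it was assigned to."""


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class AlignedSequence:
    """One query aligned to its amplicon reference, primer columns masked."""

    query_id: str
    amplicon: Amplicon
    locus: LocusSpec
    aligned_query: str
    aligned_ref: str
    #: published coordinate of the first reference base in the alignment
    ref_start: int
    masked_columns: frozenset[int] = field(default_factory=frozenset)
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("gapped query and reference differ in length")

    def column_positions(self) -> list[int | None]:
        """Published coordinate of each alignment column (None in ref gaps)."""
        out: list[int | None] = []
        idx = self.locus.to_index(self.ref_start)
        for ch in self.aligned_ref:
            if ch == "-":
                out.append(None)
            else:
                out.append(self.locus.to_coord(idx))
                idx += 1
        return out

    def base_at(self, position: int) -> str | None:
        """Query base aligned to a published reference position (None if the
        position is outside the alignment or gapped)."""
        for col, pos in enumerate(self.column_positions()):
            if pos == position:
                b = self.aligned_query[col]
                return None if b == "-" else b
        return None

    def surveyed_site_counts(self) -> tuple[int, int]:
        """(n_AT, n_GC) unmasked reference sites surveyed by this query.

        A site counts as surveyed when the reference base is A/C/G/T and the
        query carries an unambiguous A/C/G/T base in that column; ambiguous
        query bases and gaps are excluded from denominators.
        """
        n_at = n_gc = 0
        for col, pos in enumerate(self.column_positions()):
            if pos is None or col in self.masked_columns:
                continue
            r, q = self.aligned_ref[col], self.aligned_query[col]
            if r in "AT" and q in DNA_BASES:
                n_at += 1
            elif r in "GC" and q in DNA_BASES:
                n_gc += 1
        return n_at, n_gc

    def to_fasta_pair(self) -> list[tuple[str, str]]:
        """Two-row gapped FASTA export for inspection."""
        return [(f"{self.amplicon.locus}:{self.amplicon.pcr_id}", self.aligned_ref),
                (self.query_id, self.aligned_query)]


@dataclass(frozen=True)
class SubstitutionEvent:
    """One observed mismatch at an unmasked reference position."""

    gene_pos: int
    ref_base: str
    obs_base: str
    query_id: str
    amplicon_id: str

    def __post_init__(self) -> None:
        if self.ref_base == self.obs_base:
            raise ValueError("substitution with ref_base == obs_base")


def align_to_amplicon(seq: str, amplicon: Amplicon, locus: LocusSpec,
                      query_id: str = "query",
                      include_primers: bool = True) -> AlignedSequence:
    """Globally align one sequence to its amplicon reference.

    With ``include_primers`` the target is the full amplicon span and primer
    columns are masked; without it (deep-sequencing reads, whose primers were
    already trimmed) the target is the unmasked interior only.

    The query length must be within [0.5x, 2x] of the target length, guarding
    against gross mis-assignment of a sequence to the wrong amplicon.
    """
    seq = seq.upper()
    if include_primers:
        target = locus.ref_slice(amplicon.span)
        ref_start = amplicon.span[0]
    else:
        interior = locus.interior_positions(amplicon)
        target = locus.ref_slice((interior[0], interior[-1]))
        ref_start = interior[0]
    if not (0.5 * len(target) <= len(seq) <= 2 * len(target)):
        raise AlignmentInputError(
            f"length mismatch: query {query_id!r} ({len(seq)} bp) vs amplicon "
            f"{amplicon.locus}:{amplicon.pcr_id} ({len(target)} bp)")
    aln = _ALIGNER.align(target, seq)
    best = aln[0]
    aligned_ref, aligned_query = str(best[0]), str(best[1])

    masked: set[int] = set()
    if include_primers:
        f0 = locus.to_index(amplicon.primer_f_span[0])
        f1 = locus.to_index(amplicon.primer_f_span[1])
        r0 = locus.to_index(amplicon.primer_r_span[0])
        r1 = locus.to_index(amplicon.primer_r_span[1])
        idx = locus.to_index(ref_start)
        for col, ch in enumerate(aligned_ref):
            if ch != "-":
                if f0 <= idx <= f1 or r0 <= idx <= r1:
                    masked.add(col)
                idx += 1
    return AlignedSequence(query_id=query_id, amplicon=amplicon, locus=locus,
                           aligned_query=aligned_query, aligned_ref=aligned_ref,
                           ref_start=ref_start, masked_columns=frozenset(masked),
                           score=float(best.score))


def extract_events(aln: AlignedSequence,
                   ) -> tuple[list[SubstitutionEvent], list[tuple[int, str, int]]]:
    """Extract substitutions and indels from one alignment.

    Returns ``(substitutions, indels)`` where each indel is
    ``(gene_pos, kind, length)`` with kind ``"ins"`` (bases absent from the
    reference) or ``"del"`` (reference bases absent from the query) and
    gene_pos the last reference position at or before the run start.
    Masked (primer) columns contribute nothing; ambiguous query bases never
    yield substitutions.
    """
    subs: list[SubstitutionEvent] = []
    indels: list[tuple[int, str, int]] = []
    positions = aln.column_positions()
    amplicon_id = f"{aln.amplicon.locus}:{aln.amplicon.pcr_id}"

    run_kind: str | None = None
    run_len = 0
    run_pos: int | None = None
    last_pos: int | None = None

    def flush() -> None:
        nonlocal run_kind, run_len, run_pos
        if run_kind is not None and run_len > 0:
            indels.append((run_pos if run_pos is not None else aln.ref_start,
                           run_kind, run_len))
        run_kind, run_len = None, 0

    for col, pos in enumerate(positions):
        r = aln.aligned_ref[col]
        q = aln.aligned_query[col]
        masked = col in aln.masked_columns
        if pos is not None:
            last_pos = pos
        if r == "-" or q == "-":
            kind = "ins" if r == "-" else "del"
            if masked and kind == "del":
                flush()
                continue
            if run_kind == kind:
                run_len += 1
            else:
                flush()
                run_kind, run_len, run_pos = kind, 1, last_pos
            continue
        flush()
        if masked:
            continue
        if r != q and r in DNA_BASES and q in DNA_BASES:
            subs.append(SubstitutionEvent(gene_pos=pos, ref_base=r, obs_base=q,
                                          query_id=aln.query_id,
                                          amplicon_id=amplicon_id))
    flush()
    return subs, indels
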