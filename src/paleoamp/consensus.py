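"""Majority-rule consensus over aligned sequence sets or deep tallies.

Each unmasked reference position gets the most frequent symbol among the
sequences covering it (A/C/G/T or gap).  Ties between bases are written as
the IUPAC code covering the tied bases and flagged; positions where gap
strictly wins are deleted from the output string, so the consensus is plain
FASTA.  The sequence and tally pathways agree whenever the tally was built
from the same sequences, and insertions relative to the reference are
ignored (the reference frame is the consensus frame).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import AlignedSequence
from .loci import IUPAC_CODES, PositionTally


@dataclass
class ConsensusResult:
    sequence: str
    #: (gene_pos, counts {A,C,G,T,-}, called symbol, is_tie) per position
    per_position: list[tuple[int, dict[str, int], str, bool]]


def _call_column(counts: dict[str, int]) -> tuple[str, bool]:
    """Majority call for one column; ties resolve to an IUPAC code."""
    best = max(counts.values())
    if best == 0:
        raise ValueError("empty column: no observations")
    top_bases = [b for b in "ACGT" if counts[b] == best]
    gap_top = counts["-"] == best
    if gap_top and not top_bases:
        return "-", False
    if len(top_bases) == 1 and not gap_top:
        return top_bases[0], False
    return IUPAC_CODES[frozenset(top_bases)], True


def majority_consensus(aligned: Sequence[AlignedSequence] | None = None,
                       tally: PositionTally | None = None) -> ConsensusResult:
    """Per-position most-frequent-base consensus.

    Exactly one of ``aligned`` (a set of sequences aligned to one amplicon
    reference) or ``tally`` (per-position counts from deep sequencing) must
    be given.  For aligned input, only unmasked interior positions enter the
    consensus.
    """
    if (aligned is None) == (tally is None):
        raise ValueError("provide exactly one of aligned= or tally=")
    columns: list[tuple[int, dict[str, int]]] = []
    if tally is not None:
        for _, row in tally.df.iterrows():
            counts = {"A": int(row["A_tot"]), "C": int(row["C_tot"]),
                      "G": int(row["G_tot"]), "T": int(row["T_tot"]),
                      "-": int(row["gap_tot"])}
            columns.append((int(row["gene_pos"]), counts))
    else:
        if not aligned:
            raise ValueError("majority_consensus: no aligned sequences")
        locus = aligned[0].locus
        positions = locus.interior_positions(aligned[0].amplicon)
        counts_by_pos = {p: {"A": 0, "C": 0, "G": 0, "T": 0, "-": 0}
                         for p in positions}
        for aln in aligned:
            pos_of_col = aln.column_positions()
            for col, pos in enumerate(pos_of_col):
                if pos is None or pos not in counts_by_pos:
                    continue
                sym = aln.aligned_query[col]
                if sym == "-" or sym in "ACGT":
                    counts_by_pos[pos][sym if sym != "-" else "-"] += 1
        columns = [(p, counts_by_pos[p]) for p in positions]

    per_position = []
    seq_parts = []
    for pos, counts in columns:
        if sum(counts.values()) == 0:
            raise ValueError(f"no observations at gene_pos {pos}")
        called, is_tie = _call_column(counts)
        per_position.append((pos, counts, called, is_tie))
        if called != "-":
            seq_parts.append(called)
    return ConsensusResult(sequence="".join(seq_parts), per_position=per_position)


def consensus_to_fasta_record(result: ConsensusResult, name: str) -> tuple[str, str]:
    return name, result.sequence


def write_consensus_counts(result: ConsensusResult, path) -> None:
    """TSV of per-position counts and calls behind a consensus."""
    import pandas as pd
    rows = [{"gene_pos": pos, **{f"{b}_tot": counts[b] for b in "ACGT"},
             "gap_tot": counts["-"], "called": called, "is_tie": is_tie}
            for pos, counts, called, is_tie in result.per_position]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
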