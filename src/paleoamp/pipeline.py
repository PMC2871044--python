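"""End-to-end analysis of one locus: align, classify, profile damage, build
consensus, call the genotype, and trace contaminants to investigators.

The CLI wraps these functions; they are equally usable as the library
surface for scripted analyses.  Analysis is a pure function of its inputs,
so re-runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import align as _align
from . import classify as _classify
from . import consensus as _consensus
from . import damage as _damage
from .loci import (Amplicon, DiagnosticSite, InvestigatorProfile, LocusSpec,
                   PositionTally)


@dataclass
class LocusAnalysis:
    """All per-locus results of one pipeline run."""

    locus: LocusSpec
    aligned: dict[str, list[_align.AlignedSequence]] = field(default_factory=dict)
    events: dict[str, list[_align.SubstitutionEvent]] = field(default_factory=dict)
    classifications: dict[str, list[_classify.ClassifiedSequence]] = field(default_factory=dict)
    summaries: list[_classify.AmpliconSummary] = field(default_factory=list)
    mean_pct: float | None = None
    spectra: list[_damage.MisincorporationSpectrum] = field(default_factory=list)
    pooled_spectrum: _damage.MisincorporationSpectrum | None = None
    damage_freq: float | None = None
    damage_comparison: _damage.DamageComparison | None = None
    consensus: dict[str, _consensus.ConsensusResult] = field(default_factory=dict)
    allele_fractions: list[dict] = field(default_factory=list)
    genotype_calls: list[_classify.GenotypeCall] = field(default_factory=list)
    profile_matches: list[tuple[str, int, bool]] = field(default_factory=list)


def _sequence_class(aln: _align.AlignedSequence, locus: LocusSpec,
                    classified: _classify.ClassifiedSequence | None) -> str:
    """Damage-contrast class of one sequence: the haplogroup classification
    where available, else the allele carried at the target variant."""
    if classified is not None:
        return classified.label
    for site in locus.target_sites():
        base = aln.base_at(site.position)
        anc = site.ancestral_allele or site.endogenous_allele
        der = site.derived_allele or site.contaminant_allele
        if base == anc:
            return "endogenous"
        if base == der:
            return "contaminant"
    return "unclassified"


def analyze_locus(locus: LocusSpec,
                  clones: dict[str, list[tuple[str, str]]],
                  amplicons: dict[str, Amplicon],
                  tallies: Sequence[tuple[str, PositionTally]] = (),
                  profiles: Sequence[InvestigatorProfile] = (),
                  min_pcrs: int = 2,
                  derived_threshold: float = 0.10) -> LocusAnalysis:
    """Run the full analysis for one locus.

    ``clones`` maps amplification-instance ids to (clone_id, sequence) lists
    and ``amplicons`` maps the same ids to their per-instance
    :class:`Amplicon` (the instance id distinguishes replicate PCRs of one
    design, which keeps their events independent under deduplication).
    ``tallies`` are deep-sequencing runs as (amplification id, tally).
    """
    res = LocusAnalysis(locus=locus)
    has_hg_sites = bool(locus.haplogroup_sites())

    # --- alignment and event extraction -----------------------------------
    for amp_id, records in clones.items():
        amp = amplicons[amp_id]
        alns, events = [], []
        for qid, seq in records:
            aln = _align.align_to_amplicon(seq, amp, locus, query_id=qid)
            subs, _ = _align.extract_events(aln)
            alns.append(aln)
            events.extend(subs)
        res.aligned[amp_id] = alns
        res.events[amp_id] = events

    # --- classification (haplogroup loci) ---------------------------------
    if has_hg_sites:
        for amp_id, alns in res.aligned.items():
            cls = [_classify.classify_haplotype(a, locus.haplogroup_sites())
                   for a in alns]
            res.classifications[amp_id] = cls
            res.summaries.append(_classify.summarize_amplicon(
                cls, locus.name, amp_id))
        try:
            res.mean_pct = _classify.locus_mean_pct(res.summaries)
        except ValueError:
            res.mean_pct = None

    # --- per-sequence class assignment for the damage contrast ------------
    class_of: dict[str, str] = {}
    for amp_id, alns in res.aligned.items():
        cls_list = res.classifications.get(amp_id)
        for i, aln in enumerate(alns):
            c = cls_list[i] if cls_list else None
            class_of[aln.query_id] = _sequence_class(aln, locus, c)

    # --- damage spectra (deduplicated, per amplification) ------------------
    endo_events, endo_alns = [], []
    cont_events, cont_alns = [], []
    for amp_id, alns in res.aligned.items():
        for aln in alns:
            bucket = class_of[aln.query_id]
            if bucket == "endogenous":
                endo_alns.append(aln)
            elif bucket == "contaminant":
                cont_alns.append(aln)
        for ev in res.events[amp_id]:
            bucket = class_of[ev.query_id]
            if bucket == "endogenous":
                endo_events.append(ev)
            elif bucket == "contaminant":
                cont_events.append(ev)
    if res.aligned:
        for amp_id in sorted(res.aligned):
            amp = amplicons[amp_id]
            evs = [e for e in endo_events
                   if e.amplicon_id == f"{locus.name}:{amp.pcr_id}"]
            res.spectra.append(_damage.spectrum(
                _damage.dedup_events(evs),
                [(f"{locus.name}:{amp.pcr_id}", amp)], locus, label=amp_id))
        res.pooled_spectrum = _damage.pool_spectra(res.spectra, label=locus.name)
        if endo_alns:
            res.damage_freq = _damage.damage_frequency(endo_events, endo_alns)
        if endo_alns and cont_alns:
            res.damage_comparison = _damage.compare_damage(
                (endo_events, endo_alns), (cont_events, cont_alns))

    # --- consensus ---------------------------------------------------------
    for amp_id, alns in res.aligned.items():
        if alns:
            res.consensus[amp_id] = _consensus.majority_consensus(aligned=alns)
    for amp_id, tally in tallies:
        res.consensus[amp_id] = _consensus.majority_consensus(tally=tally)

    # --- allele fractions and genotype at target variants ------------------
    for site in locus.target_sites():
        pcr_counts: list[_classify.PcrAlleleCounts] = []
        anc = site.ancestral_allele or site.endogenous_allele
        der = site.derived_allele or site.contaminant_allele
        for amp_id, alns in res.aligned.items():
            n_anc = n_der = 0
            for aln in alns:
                base = aln.base_at(site.position)
                if base == anc:
                    n_anc += 1
                elif base == der:
                    n_der += 1
            pcr_counts.append(_classify.PcrAlleleCounts(
                pcr_id=amp_id, n_ancestral=n_anc, n_derived=n_der))
        for amp_id, tally in tallies:
            try:
                anc_pct, der_pct, other_pct, total = _classify.tally_allele_fractions(
                    tally, site)
            except KeyError:
                continue
            counts = tally.counts(site.position)
            pcr_counts.append(_classify.PcrAlleleCounts(
                pcr_id=amp_id, n_ancestral=counts[anc], n_derived=counts[der],
                platform="reads"))
            res.allele_fractions.append({
                "locus": locus.name, "amp_id": amp_id, "position": site.position,
                "ancestral_pct": f"{anc_pct:.2f}", "derived_pct": f"{der_pct:.2f}",
                "derived_pct_1dp": f"{der_pct:.1f}", "total_reads": total})
        if pcr_counts:
            res.genotype_calls.append(_classify.call_genotype(
                pcr_counts, site, min_pcrs=min_pcrs,
                derived_threshold=derived_threshold))

    # --- contaminant-to-investigator tracing -------------------------------
    if profiles and has_hg_sites and cont_alns:
        by_span: dict[tuple[int, int], list[_align.AlignedSequence]] = {}
        for aln in cont_alns:
            by_span.setdefault(aln.amplicon.span, []).append(aln)
        motif: list[tuple[int, str]] = []
        for alns in by_span.values():
            cons = _consensus.majority_consensus(aligned=alns)
            for pos, _counts, called, _tie in cons.per_position:
                if called in "ACGT" and called != locus.ref_base(pos):
                    motif.append((pos, called))
        res.profile_matches = _classify.match_contaminant_profile(
            sorted(set(motif)), profiles)
    return res
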