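"""Haplotype classification, per-PCR summaries, allele fractions, genotype
calling and investigator-profile matching."""

import dataclasses
import itertools

import numpy as np
import pytest

import paleoamp as pa
from conftest import align_clone


def coi_clone(coi, base_6267, base_6261):
    seq = list(coi.ref_slice(coi.amplicons[0].span))
    off = coi.to_index(coi.amplicons[0].span[0])
    seq[coi.to_index(6267) - off] = base_6267
    seq[coi.to_index(6261) - off] = base_6261
    return "".join(seq)


class TestClassifyHaplotype:
    @pytest.mark.parametrize("b6267,b6261,expected", [
        ("C", "A", "endogenous"),     # Neanderthal motif
        ("A", "C", "contaminant"),    # modern human motif
        ("C", "C", "unclassified"),   # 1 vs 1 tie
        ("A", "A", "unclassified"),
    ])
    def test_coi_motif(self, coi, b6267, b6261, expected):
        aln = align_clone(coi_clone(coi, b6267, b6261), coi)
        assert pa.classify_haplotype(aln, coi.haplogroup_sites()).label == expected

    def test_third_allele_unclassifies(self, coi):
        aln = align_clone(coi_clone(coi, "G", "A"), coi)
        assert pa.classify_haplotype(aln, coi.haplogroup_sites()).label == "unclassified"

    def test_no_site_in_amplicon_is_config_error(self, coi, mcph1):
        aln = align_clone(coi.ref_slice(coi.amplicons[0].span), coi)
        with pytest.raises(pa.classify.ConfigurationError):
            pa.classify_haplotype(aln, mcph1.diagnostic_sites)

    def test_label_swap_symmetry(self, coi):
        """Swapping endogenous/contaminant alleles at every site swaps every
        sequence's class (unclassified stays unclassified)."""
        swapped = [dataclasses.replace(s, endogenous_allele=s.contaminant_allele,
                                       contaminant_allele=s.endogenous_allele)
                   for s in coi.haplogroup_sites()]
        flip = {"endogenous": "contaminant", "contaminant": "endogenous",
                "unclassified": "unclassified"}
        for b67, b61 in itertools.product("ACGT", repeat=2):
            aln = align_clone(coi_clone(coi, b67, b61), coi)
            orig = pa.classify_haplotype(aln, coi.haplogroup_sites()).label
            assert pa.classify_haplotype(aln, swapped).label == flip[orig]


class TestSummaries:
    def test_counts_partition_input(self, coi):
        alns = [align_clone(coi_clone(coi, *m), coi, qid=f"c{i}")
                for i, m in enumerate([("C", "A")] * 3 + [("A", "C")] * 2 + [("C", "C")])]
        cls = [pa.classify_haplotype(a, coi.haplogroup_sites()) for a in alns]
        s = pa.summarize_amplicon(cls, "mtDNA-COI", "p1")
        assert (s.n_endogenous, s.n_contaminant, s.n_unclassified) == (3, 2, 1)
        assert s.n_total == len(alns)
        assert s.pct_endogenous == pytest.approx(60.0)

    def test_all_unclassified_flagged_undefined(self):
        s = pa.AmpliconSummary("L", "p", 0, 0, 5)
        assert s.pct_endogenous is None

    @pytest.mark.parametrize("pcts,expected", [
        ([100.0], 100.0),
        ([0.0, 100.0], 50.0),
        ([100, 90, 100, 85, 80, 75, 85, 95], 88.75),
    ])
    def test_locus_mean_pct(self, pcts, expected):
        summaries = [pa.AmpliconSummary("L", str(i), int(p), 100 - int(p))
                     for i, p in enumerate(pcts)]
        assert pa.locus_mean_pct(summaries) == pytest.approx(expected)

    def test_mean_requires_defined_pct(self):
        with pytest.raises(ValueError):
            pa.locus_mean_pct([pa.AmpliconSummary("L", "p", 0, 0, 3)])


class TestTallyFractions:
    def _tally(self, locus, counts_at, gene_counts):
        rows = []
        for i, pos in enumerate(locus.interior_positions(locus.amplicons[0])):
            ref = locus.ref_base(pos)
            base_counts = {"A": 0, "C": 0, "G": 0, "T": 0}
            if pos == counts_at:
                base_counts.update(gene_counts)
            else:
                base_counts[ref] = sum(gene_counts.values())
            rows.append((i + 1, pos, ref, base_counts["A"], base_counts["C"],
                         base_counts["G"], base_counts["T"], 0))
        return pa.PositionTally.from_rows(locus.name, rows)

    def test_lct_published_fractions(self, lct):
        tally = self._tally(lct, -13910, {"C": 45101, "T": 19})
        anc, der, other, total = pa.tally_allele_fractions(tally, lct.target_sites()[0])
        assert round(anc, 2) == 99.96
        assert round(der, 2) == 0.04
        assert total == 45120
        assert anc + der + other == pytest.approx(100.0)

    def test_mcph1_published_fractions(self, mcph1):
        tally = self._tally(mcph1, 37995, {"G": 12494, "C": 189})
        anc, der, other, total = pa.tally_allele_fractions(tally, mcph1.target_sites()[0])
        assert round(der, 1) == 1.5
        assert total == 12683

    def test_all_ancestral(self, lct):
        tally = self._tally(lct, -13910, {"C": 100})
        anc, der, *_ = pa.tally_allele_fractions(tally, lct.target_sites()[0])
        assert (anc, der) == (100.0, 0.0)


def oracle_call(counts, min_pcrs, threshold):
    """Independent enumeration of the genotype decision table."""
    pooled = sum(a + d for _, a, d in counts)
    if not counts or pooled == 0:
        return "undetermined"
    decisions = {}
    for allele in ("ancestral", "derived"):
        tot = sum((a if allele == "ancestral" else d) for _, a, d in counts)
        n_pcrs = sum(1 for _, a, d in counts
                     if (a if allele == "ancestral" else d) > 0)
        decisions[allele] = (n_pcrs >= min_pcrs) and (tot / pooled >= threshold)
    if decisions["ancestral"] and decisions["derived"]:
        return "heterozygous"
    if decisions["ancestral"]:
        return "homozygous_ancestral"
    if decisions["derived"]:
        return "homozygous_derived"
    return "undetermined"


class TestGenotype:
    def _call(self, counts, site, **kw):
        pcr = [pa.PcrAlleleCounts(pcr_id=p, n_ancestral=a, n_derived=d,
                                  platform="reads" if p.endswith("454") else "clones")
               for p, a, d in counts]
        return pa.call_genotype(pcr, site, **kw)

    def test_mcph1_published_counts_call_homozygous_ancestral(self, mcph1):
        site = mcph1.target_sites()[0]
        counts = [("1", 40, 0), ("3", 35, 0), ("4", 40, 0), ("5", 38, 0),
                  ("454", 12494, 189)]
        call = self._call(counts, site)
        assert call.call == "homozygous_ancestral"
        assert call.derived_fraction_clones == 0.0
        assert call.derived_fraction_reads == pytest.approx(189 / 12683)
        assert call.damage_consistent_derived is False  # G->C transversion

    def test_lct_published_counts(self, lct):
        site = lct.target_sites()[0]
        call = self._call([("1", 30, 0), ("2", 30, 0), ("454", 45101, 19)], site)
        assert call.call == "homozygous_ancestral"
        assert call.damage_consistent_derived is True  # C->T is deamination-like

    def test_balanced_heterozygous(self, lct):
        call = self._call([("1", 10, 10), ("2", 10, 10)], lct.target_sites()[0])
        assert call.call == "heterozygous"

    def test_single_pcr_derived_warns(self, lct):
        call = self._call([("1", 6, 4), ("2", 10, 0), ("3", 10, 0)],
                          lct.target_sites()[0])
        assert call.call == "homozygous_ancestral"
        assert any("derived" in w for w in call.warnings)

    def test_decision_table_matches_oracle(self, lct):
        """Exhaustive check of every branch combination of the caller against
        an independently enumerated decision table."""
        site = lct.target_sites()[0]
        count_values = [0, 1, 5, 40]
        for a1, d1, a2, d2 in itertools.product(count_values, repeat=4):
            for min_pcrs, thr in [(2, 0.10), (1, 0.10), (2, 0.5), (3, 0.05)]:
                counts = [("1", a1, d1), ("2", a2, d2)]
                got = self._call(counts, site, min_pcrs=min_pcrs,
                                 derived_threshold=thr)
                assert got.call == oracle_call(counts, min_pcrs, thr), (
                    counts, min_pcrs, thr)

    def test_no_data_undetermined(self, lct):
        assert pa.call_genotype([], lct.target_sites()[0]).call == "undetermined"


class TestDamageConsistency:
    @pytest.mark.parametrize("anc,der,expected", [
        ("C", "T", True), ("G", "A", True),   # deamination-mimicking
        ("G", "C", False),                     # the MCPH1 transversion
        ("A", "G", False), ("T", "C", False),  # type-I transitions
    ])
    def test_substitution_classes(self, anc, der, expected):
        site = pa.DiagnosticSite(position=10, endogenous_allele=anc,
                                 contaminant_allele=der, role="target_variant",
                                 ancestral_allele=anc, derived_allele=der)
        assert pa.is_damage_consistent(site) is expected


class TestProfileMatching:
    @pytest.fixture()
    def profiles(self):
        return pa.read_profile_table(pa.loci.bundled_path("synthetic_profiles.tsv"))

    def test_exact_match_flagged(self, profiles):
        motif = [(16126, "C"), (16152, "G"), (16234, "C"), (16258, "G")]
        ranked = pa.match_contaminant_profile(motif, profiles)
        assert ranked[0] == ("LL", 0, True)
        assert all(n > 0 for _, n, _ in ranked[1:])

    def test_no_match_nothing_flagged(self, profiles):
        ranked = pa.match_contaminant_profile([(16140, "G")], profiles)
        assert min(n for _, n, _ in ranked) > 0
        assert not any(exact for _, _, exact in ranked)

    def test_identical_profiles_tie(self):
        p = pa.InvestigatorProfile("x", ((100, "T"),))
        q = pa.InvestigatorProfile("y", ((100, "T"),))
        ranked = pa.match_contaminant_profile([(100, "T")], [p, q])
        assert [(r[0], r[1]) for r in ranked] == [("x", 0), ("y", 0)]

    def test_empty_comparison_errors(self):
        with pytest.raises(ValueError):
            pa.match_contaminant_profile([], [pa.InvestigatorProfile("x")])

    def test_simulated_contaminant_traced_to_carrier(self, hvr, profiles):
        """Contaminant clones simulated from the modern haplotype trace back
        to the profile that carries the full contaminant motif."""
        cfg = pa.SimConfig(locus=hvr, seed=3, c=1.0, delta=0.0, epsilon=0.0,
                           p_dropout=0.0)
        exp = pa.simulate_clone_experiment(cfg)
        res = pa.analyze_locus(hvr, exp.clones, exp.amplicons, profiles=profiles)
        assert res.profile_matches[0][0] == "LL"
        assert res.profile_matches[0][2] is True


class TestContaminationRecovery:
    def test_pooled_estimate_within_3se(self, hvr_single):
        """With no classification noise, the pooled contaminant fraction over
        2000 independent clone lineages sits within 3 binomial SE of c."""
        c = 0.12
        cfg = pa.SimConfig(locus=hvr_single, seed=2024, c=c, delta=0.0,
                           epsilon=0.0, p_dropout=0.0, n_pcrs=2000,
                           clones_per_pcr=1)
        exp = pa.simulate_clone_experiment(cfg)
        res = pa.analyze_locus(hvr_single, exp.clones, exp.amplicons)
        n_cont = sum(s.n_contaminant for s in res.summaries)
        n_tot = sum(s.n_endogenous + s.n_contaminant for s in res.summaries)
        assert n_tot == 2000
        se = np.sqrt(c * (1 - c) / n_tot)
        assert abs(n_cont / n_tot - c) <= 3 * se
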