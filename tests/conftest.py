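import dataclasses

import pytest

import paleoamp as pa


@pytest.fixture(scope="session")
def registry():
    return {locus.name: locus for locus in pa.bundled_loci()}


@pytest.fixture(scope="session")
def hvr(registry):
    return registry["mtDNA-HVRI"]


@pytest.fixture(scope="session")
def coi(registry):
    return registry["mtDNA-COI"]


@pytest.fixture(scope="session")
def lct(registry):
    return registry["LCT"]


@pytest.fixture(scope="session")
def mcph1(registry):
    return registry["MCPH1"]


@pytest.fixture(scope="session")
def toy_locus():
    """One-amplicon locus with a known interior composition: 10 A, 10 T,
    20 C, 20 G between 4 bp primers."""
    interior = "A" * 10 + "T" * 10 + "C" * 20 + "G" * 20
    ref = "AACC" + interior + "GGTT"
    amp = pa.Amplicon(locus="toy", pcr_id="p1", span=(1, 68),
                      primer_f_span=(1, 4), primer_r_span=(65, 68))
    return pa.LocusSpec(name="toy", molecule="nuclear", coord_offset=1,
                        reference=ref, amplicons=[amp]).validate()


@pytest.fixture(scope="session")
def hvr_single(hvr):
    """HVR-I locus restricted to its first amplicon (faster simulations)."""
    return dataclasses.replace(hvr, amplicons=[hvr.amplicons[0]])


def align_clone(seq, locus, amp_index=0, qid="q", include_primers=True):
    amp = locus.amplicons[amp_index]
    return pa.align_to_amplicon(seq, amp, locus, query_id=qid,
                                include_primers=include_primers)
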