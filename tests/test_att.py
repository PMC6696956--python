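"""The recombination model: core discovery, crossover inference, excision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import VNP1_CORE, VNP2_ATTL, VNP2_ATTP, VNP2_ATTR
from prophagekit import synth
from prophagekit.att import (
    AttSiteSet,
    CoreNotFoundError,
    excise,
    find_att_core,
    infer_crossover_interval,
    integrate,
    recombine,
    region_length,
)
from prophagekit.io import GenomeRecord, ProphageRegion

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


def brute_force_crossovers(attL, attR, attP):
    """Independent enumeration of all single-crossover explanations."""
    return [k for k in range(len(attL) + 1) if attR[:k] + attL[k:] == attP]


def lcs_length(a: str, b: str) -> int:
    """O(|a|*|b|) dynamic-programming longest-common-substring oracle."""
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b), dtype=np.int32)
    best = 0
    for ch in a.encode():
        cur = np.where(bv == ch, np.concatenate(([0], prev[:-1])) + 1, 0)
        best = max(best, int(cur.max()))
        prev = cur
    return best


class TestRegionLength:
    @pytest.mark.parametrize(
        "start,end,convention,expected",
        [
            (935757, 971809, "inclusive", 36053),
            (935757, 971809, "end_minus_start", 36052),
            (1496626, 1535809, "end_minus_start", 39183),
            (10, 10, "end_minus_start", 0),
        ],
    )
    def test_printed_conventions(self, start, end, convention, expected):
        assert region_length(start, end, convention) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            region_length(20, 10, "inclusive")
        with pytest.raises(ValueError):
            region_length(10, 20, "one_based")


class TestRecombine:
    def test_reconstructs_observed_attp_from_hybrid_sites(self):
        attB, attP = recombine(VNP2_ATTL, VNP2_ATTR, 23)
        assert attP == VNP2_ATTP
        assert len(attB) == len(VNP2_ATTL)

    def test_identical_sites_are_fixed_points_for_every_crossover(self):
        for k in range(len(VNP1_CORE) + 1):
            assert recombine(VNP1_CORE, VNP1_CORE, k) == (VNP1_CORE, VNP1_CORE)

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            recombine("ACGT", "ACGTA", 2)
        with pytest.raises(ValueError, match="k="):
            recombine("ACGT", "TTTT", 5)

    @given(attL=dna, attR=dna, data=st.data())
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_column_multiset_conservation_and_crossover_recovery(self, attL, attR, data):
        attR = (attR * (len(attL) // len(attR) + 1))[: len(attL)]
        k = data.draw(st.integers(0, len(attL)))
        attB, attP = recombine(attL, attR, k)
        for i in range(len(attL)):
            assert sorted((attB[i], attP[i])) == sorted((attL[i], attR[i]))
        interval = infer_crossover_interval(attL, attR, attP)
        assert interval is not None and interval[0] <= k <= interval[1]


class TestInferCrossover:
    def test_published_sites_constrain_crossover_to_12_23(self):
        assert infer_crossover_interval(VNP2_ATTL, VNP2_ATTR, VNP2_ATTP) == (12, 23)
        assert brute_force_crossovers(VNP2_ATTL, VNP2_ATTR, VNP2_ATTP) == list(range(12, 24))

    def test_degenerate_identical_sites_allow_all_crossovers(self):
        assert infer_crossover_interval(VNP1_CORE, VNP1_CORE, VNP1_CORE) == (0, len(VNP1_CORE))

    def test_unexplainable_attp_reported_as_empty(self):
        attP = "G" + VNP2_ATTP[1:] if VNP2_ATTL[0] != "G" else "T" + VNP2_ATTP[1:]
        assert infer_crossover_interval(VNP2_ATTL, VNP2_ATTR, attP) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            infer_crossover_interval("ACGT", "ACGT", "ACG")


class TestFindAttCore:
    def test_recovers_implanted_cores(self, truth):
        for region, expected in zip(truth.regions, (VNP1_CORE, VNP2_ATTR)):
            att = find_att_core(truth.genome, region)
            assert att is not None
            assert att.attL == expected
            assert att.attL == att.attR == att.attB == att.attP

    def test_no_flanking_repeat_gives_no_core_result(self, rng):
        seq = synth.random_dna(4000, 0.5, rng)
        genome = GenomeRecord("g", seq)
        region = ProphageRegion("g", 1000, 3000)
        assert find_att_core(genome, region, window=200, min_len=12) is None

    def test_agrees_with_exhaustive_substring_oracle(self):
        rng = np.random.default_rng(7)
        window = 300
        for trial in range(60):
            core_len = int(rng.integers(10, 31))
            seq = list(synth.random_dna(2000, 0.5, rng))
            core = synth.random_dna(core_len, 0.5, rng)
            start, end = 500, 1500
            seq[start : start + core_len] = core
            seq[end - core_len : end] = core
            genome = "".join(seq)
            region = ProphageRegion("g", start, end)
            att = find_att_core(genome, region, window=window, min_len=10)
            wl = genome[start - window : start + window]
            wr = genome[end - window : end + window]
            oracle_len = lcs_length(wl, wr)
            assert att is not None
            assert att.core_length == oracle_len >= core_len
            assert att.attL in wl and att.attL in wr


class TestExciseIntegrate:
    def _att(self, core):
        return AttSiteSet(attL=core, attR=core)

    def test_host_keeps_single_core_copy(self, truth):
        region = truth.regions[0]
        att = self._att(region.att_core)
        host, circle = excise(truth.genome, region, att, k=0)
        assert host.sequence.count(region.att_core) == 1
        assert circle.sequence.startswith(region.att_core)

    def test_material_conservation_on_random_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(100):
            core = synth.random_dna(int(rng.integers(10, 25)), 0.5, rng)
            spec = synth.PhageSpec("VNP1", 2000, 2000 + int(rng.integers(100, 2000)), core)
            t = synth.generate_host_genome(8000, [spec], gc=0.5, seed=int(rng.integers(2**31)))
            k = int(rng.integers(0, len(core) + 1))
            host, circle = excise(t.genome, t.regions[0], self._att(core), k)
            assert len(host) + len(circle) == len(t.genome)

    def test_identical_core_round_trip_is_identity(self, truth):
        region = truth.regions[1]
        core = region.att_core
        att = AttSiteSet(attL=core, attR=core, attB=core, attP=core)
        host, circle = excise(truth.genome, region, att, k=7)
        rotated = GenomeRecord(circle.id, circle.sequence[13:] + circle.sequence[:13])
        back = integrate(host, region.start, rotated, att, k=7)
        assert back.sequence == truth.genome.sequence

    def test_impaired_core_round_trip_conserves_junction_multisets(self, rng):
        # Implant genuinely different attL/attR (the impaired 26-bp site).
        k = 15
        attB, attP = recombine(VNP2_ATTL, VNP2_ATTR, k)
        left = synth.random_dna(1000, 0.5, rng)
        interior = synth.random_dna(3000, 0.5, rng)
        right = synth.random_dna(1000, 0.5, rng)
        genome = GenomeRecord("g", left + VNP2_ATTL + interior + VNP2_ATTR + right)
        region = ProphageRegion("g", 1000, 1000 + 26 + 3000 + 26, "VNP2")
        att = AttSiteSet(attL=VNP2_ATTL, attR=VNP2_ATTR)
        host, circle = excise(genome, region, att, k)
        assert host.sequence[1000:1026] == attB
        assert circle.sequence[:26] == attP
        back = integrate(host, 1000, circle, AttSiteSet(VNP2_ATTL, VNP2_ATTR, attB, attP), k)
        assert len(back) == len(genome)
        for i in range(26):
            site_l, site_r = back.sequence[1000 + i], back.sequence[1000 + 26 + 3000 + i]
            assert sorted((site_l, site_r)) == sorted((VNP2_ATTL[i], VNP2_ATTR[i]))

    def test_missing_cores_raise(self, truth):
        region = truth.regions[0]
        with pytest.raises(CoreNotFoundError):
            excise(truth.genome, region, self._att("A" * 14), k=0)
        host, circle = excise(truth.genome, region, self._att(region.att_core), k=0)
        with pytest.raises(CoreNotFoundError):
            integrate(host, 12345, circle, self._att(region.att_core), k=0)
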