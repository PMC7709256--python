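"""NG86 estimator: hand-derived values, pathway-enumeration oracle, invariants."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleowgd.ks import (
    CodonAlignment,
    MIN_USABLE_ANCHORS,
    block_median_ks,
    codon_align,
    ng86,
    pair_ks,
)

NTS = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
CODE = {}
from Bio.Data.CodonTable import standard_dna_table as _t  # noqa: E402
CODE.update(_t.forward_table)
NONSTOP = sorted(c for c in ("".join(x) for x in __import__("itertools").product(NTS, repeat=3)) if c not in STOPS)


# ---------------------------------------------------------------------------
# independent oracle: direct string-level NG86, no caching, no shortcuts
# ---------------------------------------------------------------------------

def oracle_sites(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        syn, valid = 0, 0
        for nt in NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOPS:
                continue
            valid += 1
            syn += CODE[alt] == CODE[codon]
        if valid:
            s += syn / valid
    return s


def oracle_differences(c1: str, c2: str) -> tuple[float, float]:
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                ok = False
                break
            if CODE[nxt] == CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return float("nan"), float("nan")  # all-blocked pairs checked separately
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def oracle_ng86(codons_a, codons_b):
    S = 0.5 * (sum(map(oracle_sites, codons_a)) + sum(map(oracle_sites, codons_b)))
    N = 3 * len(codons_a) - S
    Sd = Nd = 0.0
    for c1, c2 in zip(codons_a, codons_b):
        sd, nd = oracle_differences(c1, c2)
        Sd += sd
        Nd += nd
    return N, S, Nd, Sd


class TestNg86:
    def test_identical_sequences_zero_rates(self):
        est = pair_ks("TTTGGGAAA", "TTTGGGAAA")
        assert est.Sd == est.Nd == 0.0
        assert est.ks == est.ka == 0.0
        assert not est.saturated

    def test_hand_derived_single_synonymous_change(self):
        # TTT/TTC (Phe, 1/3 syn site), GGG (1), AAA (1/3): S = 5/3
        est = pair_ks("TTTGGGAAA", "TTCGGGAAA")
        assert est.S == pytest.approx(5 / 3)
        assert est.N == pytest.approx(22 / 3)
        assert est.Sd == 1.0 and est.Nd == 0.0
        assert est.pS == pytest.approx(0.6)
        assert est.ks == pytest.approx(-0.75 * np.log(0.2))
        assert est.ka == 0.0

    def test_site_conservation_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            ca = [NONSTOP[i] for i in rng.integers(0, len(NONSTOP), n)]
            cb = [NONSTOP[i] for i in rng.integers(0, len(NONSTOP), n)]
            est = ng86(CodonAlignment("a", "b", ca, cb))
            assert est.N + est.S == pytest.approx(3 * n, abs=1e-9)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(NONSTOP), min_size=1, max_size=3),
           st.data())
    def test_matches_pathway_enumeration_oracle(self, codons_a, data):
        codons_b = [data.draw(st.sampled_from(NONSTOP)) for _ in codons_a]
        est = ng86(CodonAlignment("a", "b", codons_a, codons_b))
        N, S, Nd, Sd = oracle_ng86(codons_a, codons_b)
        if not np.isnan(Nd):
            assert est.N == pytest.approx(N)
            assert est.S == pytest.approx(S)
            assert est.Nd == pytest.approx(Nd)
            assert est.Sd == pytest.approx(Sd)

    def test_saturation_flag(self):
        # wildly different codons at every position push pS to saturation
        ca = ["TTT"] * 8
        cb = ["AGC"] * 8
        est = ng86(CodonAlignment("a", "b", ca, cb))
        assert est.saturated and est.ks is None


class TestCodonAlign:
    def test_identical_cds_keeps_all_codons(self):
        cds = "ATGGCTGCTGCTGCTGCTGCTGCTGCTTAT"  # 10 codons
        aln = codon_align(cds, cds)
        assert aln.n_codons == 10
        assert aln.codons_a == aln.codons_b

    def test_insertion_column_dropped(self):
        a = "ATGTGTCATGAACGT"            # 5 codons
        b = "ATGTGTAAACATGAACGT"         # same with 1-codon insertion (AAA)
        aln = codon_align(a, b, "a", "b")
        assert aln.n_codons == 5
        assert aln.codons_a == [a[i:i + 3] for i in range(0, 15, 3)]

    def test_internal_stop_names_the_gene(self):
        with pytest.raises(ValueError, match="badgene"):
            codon_align("ATGTAAAAATTT", "ATGAAAAAATTT", "badgene", "b")

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            codon_align("ATGAA", "ATGAAA")


class _FakeBlock:
    def __init__(self, coords):
        self.block_id = 1
        self.anchor_coords = coords


class TestBlockMedian:
    def _estimates(self, ks_values, saturated_from=None):
        ests = {}
        for i, v in enumerate(ks_values):
            sat = saturated_from is not None and i >= saturated_from
            e = pair_ks("ATGAAA", "ATGAAA", f"a{i}", f"b{i}")
            e.ks = None if sat else v
            e.saturated = sat
            ests[(f"a{i}", f"b{i}")] = e
        return ests

    def _block(self, n):
        return _FakeBlock([(f"a{i}", i, f"b{i}", i) for i in range(n)])

    def test_odd_count_median(self):
        est = self._estimates([0.1, 0.2, 0.3])
        assert block_median_ks(self._block(3), est) == pytest.approx(0.2)

    def test_even_count_median_mean_of_central_pair(self):
        est = self._estimates([0.1, 0.2, 0.3, 0.4])
        assert block_median_ks(self._block(4), est) == pytest.approx(0.25)

    def test_mostly_saturated_block_uninformative(self):
        est = self._estimates([0.1, 0.2, 0.3, 0.4, 0.5], saturated_from=2)
        assert MIN_USABLE_ANCHORS == 3
        assert block_median_ks(self._block(5), est) is None
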