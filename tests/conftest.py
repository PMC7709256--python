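"""Shared fixtures: small simulated study systems reused across test modules."""

import pytest

import paleowgd as pw
from paleowgd.simulate import (
    one_two_four_scenario,
    run_scenario,
)


@pytest.fixture(scope="session")
def loss_free_wgd():
    """One loss-free WGD at 60 MY on a 120-gene ancestor: every gene has
    exactly one twin, the cleanest possible synteny/Ks substrate."""
    scen = pw.SimScenario(
        events=[pw.ScenarioEvent("wgd", 60.0, "root", name="alpha")],
        n_chromosomes=2,
        n_genes=120,
        codons_per_gene=100,
        seed=101,
    )
    genomes, truth = run_scenario(scen)
    return genomes["root"], truth


@pytest.fixture(scope="session")
def loss_free_pairs(loss_free_wgd):
    genome, _truth = loss_free_wgd
    return pw.find_homolog_pairs([genome])


@pytest.fixture(scope="session")
def ots_system():
    """Outgroup/mid/ingroup 1:2:4 lineage-specific system with homology and
    blocks precomputed (the expensive shared substrate for synteny and
    phylogeny tests)."""
    scen = one_two_four_scenario(n_genes=120, codons_per_gene=300, seed=42)
    genomes, truth = run_scenario(scen)
    O, M, I = genomes["O"], genomes["M"], genomes["I"]
    pairs = pw.find_homolog_pairs([O, M, I], genome_pairs=[("O", "M"), ("O", "I")])
    blocks = pw.detect_blocks(pairs, O, M) + pw.detect_blocks(pairs, O, I)
    return {
        "genomes": genomes,
        "truth": truth,
        "pairs": pairs,
        "blocks": blocks,
        "scenario": scen,
    }
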