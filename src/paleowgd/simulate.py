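"""Genome-evolution simulator: speciation, whole-genome duplication, fractionation.

Simulates a set of annotated genomes descending from a common ancestor through
a scripted series of speciations and WGDs, with post-WGD gene loss
(fractionation), segmental inversions/translocations, and codon sequences
diverging under a synonymous molecular clock: two copies separated ``t`` years
accumulate an expected ``2*r*t`` synonymous substitutions per synonymous site
(Poisson counts, multiple hits allowed, so downstream NG86 estimates saturate
naturally).  A machine-readable truth log records the duplication origin of
every extant gene and yields exact expected Ks for any gene pair.

Synonymous events are drawn only among single-nucleotide codon changes that
preserve the amino acid; nonsynonymous events change it; substitutions to or
from stop codons never occur.  Site weighting matches the NG86 site
definition (per position, synonymous fraction = synonymous one-step changes /
valid one-step changes), so the simulator's rate parameter and the estimator's
"per synonymous site" scale agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .genome import AnnotatedGenome, Gene

__all__ = [
    "ScenarioEvent",
    "SimScenario",
    "SimTruth",
    "simulate_ancestor",
    "run_scenario",
    "write_truth_table",
    "outgroup_ingroup_scenario",
    "sister_species_scenario",
    "one_two_four_scenario",
    "shared_wgd_scenario",
]

# Default rearrangement intensity: ~0.5 segmental ops per 100 genes per event
# keeps the per-event rearranged gene fraction near 5%, giving block-size
# erosion comparable to deep plant genome comparisons without overwhelming
# desk-scale genomes.
DEFAULT_REARRANGEMENT_RATE = 0.5

_NTS = "ACGT"
_CODONS = [a + b + c for a in _NTS for b in _NTS for c in _NTS]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}
_STOPS = set(standard_dna_table.stop_codons)
_AA = {c: standard_dna_table.forward_table[c] for c in _CODONS if c not in _STOPS}
_NONSTOP = [_CODON_INDEX[c] for c in _CODONS if c not in _STOPS]


def _build_tables():
    """Per codon and position: synonymous / nonsynonymous one-step neighbors and
    NG86 site fractions (stop-excluded)."""
    syn_alts = [[[] for _ in range(3)] for _ in range(64)]
    non_alts = [[[] for _ in range(3)] for _ in range(64)]
    syn_frac = np.zeros((64, 3))
    for c in _CODONS:
        ci = _CODON_INDEX[c]
        if c in _STOPS:
            continue
        for pos in range(3):
            n_valid = 0
            for nt in _NTS:
                if nt == c[pos]:
                    continue
                alt = c[:pos] + nt + c[pos + 1:]
                if alt in _STOPS:
                    continue
                n_valid += 1
                if _AA[alt] == _AA[c]:
                    syn_alts[ci][pos].append(_CODON_INDEX[alt])
                else:
                    non_alts[ci][pos].append(_CODON_INDEX[alt])
            if n_valid:
                syn_frac[ci, pos] = len(syn_alts[ci][pos]) / n_valid
    return syn_alts, non_alts, syn_frac


_SYN_ALTS, _NON_ALTS, _SYN_FRAC = _build_tables()
_SYN_SITES = _SYN_FRAC.sum(axis=1)  # synonymous sites per codon
_NON_SITES = 3.0 - _SYN_SITES


# ---------------------------------------------------------------------------
# scenario description
# ---------------------------------------------------------------------------

@dataclass
class ScenarioEvent:
    """One event on the lineage tree.

    ``time_my`` is the age in million years before present.  For a speciation,
    ``daughters`` names the two lineages replacing ``lineage``; for a WGD,
    ``loss_fraction`` is the probability that each gene on the *new* duplicate
    chromosomes is lost (fractionation).  ``rearrangement_rate`` is the
    expected number of segmental inversions/translocations per 100 genes
    applied to the affected lineage(s) right after the event.
    """

    kind: str  # 'speciation' | 'wgd'
    time_my: float
    lineage: str
    name: str = ""
    daughters: tuple[str, str] | None = None
    loss_fraction: float = 0.0
    rearrangement_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("speciation", "wgd"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "speciation" and (self.daughters is None or len(self.daughters) != 2):
            raise ValueError("speciation event needs two daughter labels")
        if self.kind == "wgd" and not (0.0 <= self.loss_fraction < 1.0):
            raise ValueError("loss_fraction must be in [0, 1)")
        if self.kind == "speciation" and self.loss_fraction:
            raise ValueError("loss_fraction only applies to WGD events")
        if not self.name:
            self.name = f"{self.kind}@{self.time_my:g}MY({self.lineage})"


@dataclass
class SimScenario:
    """A full simulation recipe: ancestor size, event script, and clock rates.

    ``synonymous_rate`` is r, substitutions per synonymous site per year;
    ``nonsynonymous_rate`` the analogue for nonsynonymous sites (default a
    Ka/Ks of ~0.2, typical of purifying selection on plant proteomes).
    """

    events: list[ScenarioEvent]
    n_chromosomes: int = 2
    n_genes: int = 500
    codons_per_gene: int = 100
    synonymous_rate: float = 3.25e-9
    nonsynonymous_rate: float = 6.5e-10
    seed: int = 0
    root_label: str = "root"

    def validate(self) -> None:
        if self.synonymous_rate <= 0:
            raise ValueError("synonymous_rate must be > 0")
        if self.nonsynonymous_rate < 0:
            raise ValueError("nonsynonymous_rate must be >= 0")
        if self.n_genes < self.n_chromosomes:
            raise ValueError("need n_genes >= n_chromosomes")
        live = {self.root_label}
        last_time: dict[str, float] = {self.root_label: float("inf")}
        for ev in self.events:
            if ev.lineage not in live:
                raise ValueError(f"event {ev.name} on unknown lineage {ev.lineage!r}")
            if ev.time_my >= last_time[ev.lineage]:
                raise ValueError(
                    f"event times must strictly decrease along a lineage "
                    f"({ev.name} at {ev.time_my} MY)"
                )
            if ev.kind == "speciation":
                assert ev.daughters is not None
                live.discard(ev.lineage)
                for d in ev.daughters:
                    if d in live:
                        raise ValueError(f"daughter label {d!r} already in use")
                    live.add(d)
                    last_time[d] = ev.time_my
            else:
                last_time[ev.lineage] = ev.time_my


# ---------------------------------------------------------------------------
# truth log
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth for a simulated scenario.

    ``histories`` maps (tip, gene_id) to the ordered (event_index, side)
    branch choices the gene's copy lineage took; the divergence time of two
    genes is the age of the first event at which their histories differ.
    """

    events: list[ScenarioEvent]
    histories: dict[tuple[str, str], tuple[tuple[int, int], ...]]
    ancestor_of: dict[tuple[str, str], str]
    synonymous_rate: float
    seed: int

    def origin(self, tip: str, gene_id: str) -> tuple[str, float]:
        """(origin_event_name, age_MY) of the WGD that created this gene copy,
        or ('ancestral', nan) if the gene is not a retained duplicate copy."""
        for evi, side in reversed(self.histories[(tip, gene_id)]):
            if self.events[evi].kind == "wgd" and side == 1:
                return self.events[evi].name, self.events[evi].time_my
        return "ancestral", float("nan")

    def divergence_time_my(self, tip_a: str, gene_a: str, tip_b: str, gene_b: str) -> float:
        """Age (MY) of the event separating two gene copies; nan if unrelated."""
        if self.ancestor_of[(tip_a, gene_a)] != self.ancestor_of[(tip_b, gene_b)]:
            return float("nan")
        ha = self.histories[(tip_a, gene_a)]
        hb = self.histories[(tip_b, gene_b)]
        for x, y in zip(ha, hb):
            if x != y:
                return self.events[x[0]].time_my
        raise ValueError(f"genes {gene_a}/{gene_b} share an identical copy history")

    def expected_ks(self, tip_a: str, gene_a: str, tip_b: str, gene_b: str) -> float:
        """2*r*t for the pair's true divergence time t."""
        t = self.divergence_time_my(tip_a, gene_a, tip_b, gene_b)
        return 2.0 * self.synonymous_rate * t * 1e6


def write_truth_table(truth: SimTruth, path) -> None:
    lines = ["gene_id\ttip\tancestor_id\torigin_event\torigin_time_MY"]
    for (tip, gid), _h in sorted(truth.histories.items()):
        ev, t = truth.origin(tip, gid)
        lines.append(f"{gid}\t{tip}\t{truth.ancestor_of[(tip, gid)]}\t{ev}\t{t:g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------

_GENE_SPACING = 500  # nt between laid-out genes


def _random_codons(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random stop-free codon index array of length n, starting with ATG."""
    out = rng.choice(_NONSTOP, size=n).astype(np.int16)
    out[0] = _CODON_INDEX["ATG"]
    return out


def _codons_to_str(codons: np.ndarray) -> str:
    return "".join(_CODONS[c] for c in codons)


def simulate_ancestor(
    n_chromosomes: int, n_genes: int, codons_per_gene: int, seed: int
) -> AnnotatedGenome:
    """A random ancestral genome: genes evenly partitioned over chromosomes,
    non-overlapping 1-based coordinates, stop-free CDS of the stated length."""
    if n_chromosomes <= 0 or n_genes <= 0 or codons_per_gene <= 0:
        raise ValueError("counts must be positive")
    if codons_per_gene < 30:
        raise ValueError("need codons_per_gene >= 30")
    if n_genes < n_chromosomes:
        raise ValueError("need n_genes >= n_chromosomes")
    rng = np.random.default_rng(seed)
    genome = AnnotatedGenome(label="ancestor")
    per_chrom = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        per_chrom[i] += 1
    gid = 0
    for ci, count in enumerate(per_chrom):
        pos = 1
        for _ in range(count):
            gid += 1
            codons = _random_codons(rng, codons_per_gene)
            length = 3 * codons_per_gene
            strand = "+" if rng.random() < 0.5 else "-"
            genome.add(
                Gene(f"g{gid:06d}", f"chr{ci + 1:02d}", pos, pos + length - 1, strand,
                     _codons_to_str(codons))
            )
            pos += length + _GENE_SPACING
    return genome


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _evolve_gene(codons: np.ndarray, rng: np.random.Generator,
                 syn_expect: float, non_expect: float) -> None:
    """Apply Poisson numbers of synonymous/nonsynonymous substitutions in place.

    ``syn_expect`` is r*dt (expected substitutions per synonymous site);
    events are placed proportionally to NG86 site weights and the weights are
    refreshed after every hit, so multiple hits in one codon are possible.
    """
    for expect, sites, alts in (
        (syn_expect, _SYN_SITES, _SYN_ALTS),
        (non_expect, _NON_SITES, _NON_ALTS),
    ):
        if expect <= 0:
            continue
        total_sites = float(sites[codons].sum())
        n_events = rng.poisson(expect * total_sites)
        for _ in range(n_events):
            w = sites[codons]
            cum = np.cumsum(w)
            if cum[-1] <= 0:
                break
            k = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            k = min(k, len(codons) - 1)
            # choose position within codon by site weight, then a target state
            ci = int(codons[k])
            fracs = (_SYN_FRAC[ci] if sites is _SYN_SITES else 1.0 - _SYN_FRAC[ci]).copy()
            # positions with no valid change at all carry zero weight either way
            for pos in range(3):
                if not alts[ci][pos]:
                    fracs[pos] = 0.0
            if fracs.sum() <= 0:
                continue
            pos = int(np.searchsorted(np.cumsum(fracs), rng.random() * fracs.sum(),
                                      side="right"))
            pos = min(pos, 2)
            choices = alts[ci][pos]
            codons[k] = choices[int(rng.integers(len(choices)))]


# ---------------------------------------------------------------------------
# scenario execution
# ---------------------------------------------------------------------------

@dataclass
class _SimGene:
    gid: int
    codons: np.ndarray
    strand: str
    ancestor: str
    history: tuple[tuple[int, int], ...] = ()


class _LineageState:
    def __init__(self, chroms: list[list[_SimGene]], time_my: float):
        self.chroms = chroms
        self.time_my = time_my  # age to which sequences have been evolved

    def n_genes(self) -> int:
        return sum(len(c) for c in self.chroms)

    def clone(self) -> "_LineageState":
        return _LineageState(
            [[_SimGene(g.gid, g.codons.copy(), g.strand, g.ancestor, g.history)
              for g in chrom] for chrom in self.chroms],
            self.time_my,
        )


def _rearrange(state: _LineageState, rate_per_100: float, rng: np.random.Generator) -> None:
    """Segmental inversions (2-20 genes) and translocations to another chromosome."""
    if rate_per_100 <= 0:
        return
    n_ops = rng.poisson(rate_per_100 * state.n_genes() / 100.0)
    for _ in range(n_ops):
        sizes = [len(c) for c in state.chroms]
        eligible = [i for i, s in enumerate(sizes) if s >= 2]
        if not eligible:
            return
        ci = eligible[int(rng.integers(len(eligible)))]
        chrom = state.chroms[ci]
        seg_len = min(int(rng.integers(2, 21)), len(chrom))
        start = int(rng.integers(0, len(chrom) - seg_len + 1))
        seg = chrom[start:start + seg_len]
        if rng.random() < 0.5 or len(state.chroms) < 2:
            # inversion: reverse order and flip strands
            for g in seg:
                g.strand = "+" if g.strand == "-" else "-"
            chrom[start:start + seg_len] = seg[::-1]
        else:
            others = [i for i in range(len(state.chroms)) if i != ci]
            cj = others[int(rng.integers(len(others)))]
            del chrom[start:start + seg_len]
            dest = state.chroms[cj]
            at = int(rng.integers(0, len(dest) + 1))
            dest[at:at] = seg


def _evolve_to(state: _LineageState, new_time_my: float, scen: SimScenario,
               rng: np.random.Generator) -> None:
    dt_years = (state.time_my - new_time_my) * 1e6
    if dt_years < 0:
        raise ValueError("time must move toward the present")
    if dt_years > 0:
        syn = scen.synonymous_rate * dt_years
        non = scen.nonsynonymous_rate * dt_years
        for chrom in state.chroms:
            for g in chrom:
                _evolve_gene(g.codons, rng, syn, non)
    state.time_my = new_time_my


def run_scenario(scenario: SimScenario) -> tuple[dict[str, AnnotatedGenome], SimTruth]:
    """Execute the event script and return tip genomes plus the truth log."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)

    ancestor = simulate_ancestor(
        scenario.n_chromosomes, scenario.n_genes, scenario.codons_per_gene,
        seed=int(rng.integers(2**31)),
    )
    start_time = (max(ev.time_my for ev in scenario.events) if scenario.events else 0.0)
    gid_counter = ancestor.n_genes()
    chroms: list[list[_SimGene]] = []
    for _chrom, genes in ancestor.chromosomes().items():
        chroms.append(
            [_SimGene(int(g.gene_id[1:]),
                      np.array([_CODON_INDEX[g.cds[i:i + 3]] for i in range(0, len(g.cds), 3)],
                               dtype=np.int16),
                      g.strand, g.gene_id)
             for g in genes]
        )
    live: dict[str, _LineageState] = {scenario.root_label: _LineageState(chroms, start_time)}

    for evi, ev in enumerate(scenario.events):
        state = live[ev.lineage]
        _evolve_to(state, ev.time_my, scenario, rng)
        if ev.kind == "speciation":
            assert ev.daughters is not None
            d1, d2 = ev.daughters
            s1, s2 = state, state.clone()
            for side, s in ((0, s1), (1, s2)):
                for chrom in s.chroms:
                    for g in chrom:
                        g.history = g.history + ((evi, side),)
            del live[ev.lineage]
            live[d1], live[d2] = s1, s2
            for s in (s1, s2):
                _rearrange(s, ev.rearrangement_rate, rng)
        else:  # wgd
            new_chroms: list[list[_SimGene]] = []
            for chrom in state.chroms:
                dup: list[_SimGene] = []
                for g in chrom:
                    g.history = g.history + ((evi, 0),)
                    if rng.random() < ev.loss_fraction:
                        continue  # duplicate copy lost (fractionation)
                    gid_counter += 1
                    dup.append(_SimGene(gid_counter, g.codons.copy(), g.strand,
                                        g.ancestor, g.history[:-1] + ((evi, 1),)))
                if dup:
                    new_chroms.append(dup)
            state.chroms.extend(new_chroms)
            _rearrange(state, ev.rearrangement_rate, rng)

    histories: dict[tuple[str, str], tuple[tuple[int, int], ...]] = {}
    ancestor_of: dict[tuple[str, str], str] = {}
    genomes: dict[str, AnnotatedGenome] = {}
    for tip in sorted(live):
        state = live[tip]
        _evolve_to(state, 0.0, scenario, rng)
        genome = AnnotatedGenome(label=tip)
        for ci, chrom in enumerate(state.chroms):
            pos = 1
            for g in chrom:
                gid = f"{tip}_g{g.gid:06d}"
                cds = _codons_to_str(g.codons)
                genome.add(Gene(gid, f"chr{ci + 1:02d}", pos, pos + len(cds) - 1,
                                g.strand, cds))
                histories[(tip, gid)] = g.history
                ancestor_of[(tip, gid)] = g.ancestor
                pos += len(cds) + _GENE_SPACING
        genomes[tip] = genome

    truth = SimTruth(list(scenario.events), histories, ancestor_of,
                     scenario.synonymous_rate, scenario.seed)
    return genomes, truth


# ---------------------------------------------------------------------------
# canned study scenarios
# ---------------------------------------------------------------------------

def outgroup_ingroup_scenario(
    n_genes: int = 1000,
    wgd_times: tuple[float, float] = (80.0, 60.0),
    loss_fraction: float = 0.2,
    split_my: float = 120.0,
    rearrangement_rate: float = DEFAULT_REARRANGEMENT_RATE,
    seed: int = 0,
    **kwargs,
) -> SimScenario:
    """An unduplicated outgroup vs. an ingroup with two lineage-specific WGDs
    (the A. trichopoda-like 1:4 configuration).  Tips: 'out', 'in'."""
    t1, t2 = wgd_times
    return SimScenario(
        events=[
            ScenarioEvent("speciation", split_my, "root", daughters=("out", "in"),
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("wgd", t1, "in", name="alpha", loss_fraction=loss_fraction,
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("wgd", t2, "in", name="beta", loss_fraction=loss_fraction,
                          rearrangement_rate=rearrangement_rate),
        ],
        n_genes=n_genes, seed=seed, **kwargs,
    )


def sister_species_scenario(
    n_genes: int = 1000,
    wgd_times: tuple[float, float] = (80.0, 60.0),
    loss_fraction: float = 0.3,
    split_my: float = 30.0,
    rearrangement_rate: float = DEFAULT_REARRANGEMENT_RATE,
    seed: int = 0,
    **kwargs,
) -> SimScenario:
    """Two sister genomes sharing the same two ancestral WGDs, then diverging
    (the T. sinense / T. aralioides-like 1:1 configuration).  Tips: 'sisA',
    'sisB'."""
    t1, t2 = wgd_times
    return SimScenario(
        events=[
            ScenarioEvent("wgd", t1, "root", name="alpha", loss_fraction=loss_fraction,
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("wgd", t2, "root", name="beta", loss_fraction=loss_fraction,
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("speciation", split_my, "root", daughters=("sisA", "sisB"),
                          rearrangement_rate=rearrangement_rate),
        ],
        n_genes=n_genes, seed=seed, **kwargs,
    )


def one_two_four_scenario(
    n_genes: int = 150,
    codons_per_gene: int = 300,
    loss_fraction: float = 0.2,
    rearrangement_rate: float = DEFAULT_REARRANGEMENT_RATE,
    seed: int = 0,
    **kwargs,
) -> SimScenario:
    """Lineage-specific WGDs in a 1:2:4 design: outgroup 'O' (no WGD), mid
    'M' (one WGD after its split), ingroup 'I' (two WGDs after its split).
    Every duplication postdates every speciation; event ages follow the real
    configuration this emulates (deep angiosperm splits ~150/120 MY, WGDs at
    82/59 MY in the ingroup and ~65 MY in the mid lineage)."""
    return SimScenario(
        events=[
            ScenarioEvent("speciation", 150.0, "root", daughters=("O", "MI"),
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("speciation", 120.0, "MI", daughters=("M", "I"),
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("wgd", 82.0, "I", name="alpha", loss_fraction=loss_fraction,
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("wgd", 65.0, "M", name="mid_wgd", loss_fraction=loss_fraction,
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("wgd", 59.0, "I", name="beta", loss_fraction=loss_fraction,
                          rearrangement_rate=rearrangement_rate),
        ],
        n_genes=n_genes, codons_per_gene=codons_per_gene, seed=seed, **kwargs,
    )


def shared_wgd_scenario(
    n_genes: int = 150,
    codons_per_gene: int = 300,
    loss_fraction: float = 0.2,
    rearrangement_rate: float = DEFAULT_REARRANGEMENT_RATE,
    seed: int = 0,
    **kwargs,
) -> SimScenario:
    """A WGD shared by 'M' and 'I' (predating their split) plus one WGD
    specific to 'I': gene trees should join each M copy with the I copies
    descending from the same ancestral WGD copy."""
    return SimScenario(
        events=[
            ScenarioEvent("speciation", 120.0, "root", daughters=("O", "MI"),
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("wgd", 80.0, "MI", name="alpha_shared",
                          loss_fraction=loss_fraction,
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("speciation", 50.0, "MI", daughters=("M", "I"),
                          rearrangement_rate=rearrangement_rate),
            ScenarioEvent("wgd", 40.0, "I", name="beta", loss_fraction=loss_fraction,
                          rearrangement_rate=rearrangement_rate),
        ],
        n_genes=n_genes, codons_per_gene=codons_per_gene, seed=seed, **kwargs,
    )
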