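"""Configuration, the orchestrated end-to-end pipeline, and the run manifest.

Stages: homology -> synteny -> Ks -> peak fitting/dating, plus the three-genome
topology test when outgroup/mid/ingroup roles are configured.  Every stage
writes its table under ``output_dir``; the manifest records the config echo,
seeds and a sha256 per output, and reruns with the same config and seed are
byte-identical (single process, one seed propagated to every stochastic
stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median

import yaml

from . import dating, homology, ks, phylo, synteny
from .genome import AnnotatedGenome, read_genome

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "read_pair_table", "anchor_ks"]

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; mirrors the YAML config file."""

    genomes: list[dict]  # {label, fasta, gff}
    output_dir: str = "paleowgd_out"
    roles: dict | None = None  # {outgroup, mid, ingroup}
    min_identity: float = 0.3
    top_n_hits: int = 5
    min_anchors: int = synteny.DEFAULT_MIN_ANCHORS
    max_gap: int = synteny.DEFAULT_MAX_GAP
    match_score: float = synteny.DEFAULT_MATCH_SCORE
    gap_penalty: float = synteny.DEFAULT_GAP_PENALTY
    ks_max: float = dating.DEFAULT_KS_MAX
    max_components: int = dating.DEFAULT_MAX_COMPONENTS
    calibration_median_ks: float | None = None
    calibration_divergence_time_my: float | None = None
    calibration_pair: list[str] | None = None  # genome labels used for internal calibration
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        flat = dict(raw)
        stages = {}
        for key in ("homology", "synteny", "ks", "dating"):
            stages.update(flat.pop(key, {}) or {})
        cal = stages.pop("calibration", None) or {}
        cfg = cls(
            genomes=flat.pop("genomes"),
            output_dir=flat.pop("output_dir", "paleowgd_out"),
            roles=flat.pop("roles", None),
            **{k: v for k, v in {**stages, **flat}.items()},
        )
        if cal:
            cfg.calibration_median_ks = cal.get("median_ks")
            cfg.calibration_divergence_time_my = cal.get("divergence_time_my")
            cfg.calibration_pair = cal.get("pair")
        return cfg

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    checksums: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True,
                                         default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_pair_table(path) -> list[homology.HomologPair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("gene_a")
        for line in fh:
            ga, gb, la, lb, score, ident, rel = line.rstrip("\n").split("\t")
            pairs.append(homology.HomologPair(ga, gb, la, lb, float(score),
                                              float(ident), rel))
    return pairs


def anchor_ks(blocks, genomes_by_label) -> dict[tuple[str, str], ks.KsEstimate]:
    """NG86 estimate for every distinct anchor pair across the given blocks."""
    estimates: dict[tuple[str, str], ks.KsEstimate] = {}
    cds = {}
    for b in blocks:
        ga_genome = genomes_by_label[b.genome_a]
        gb_genome = genomes_by_label[b.genome_b]
        for g_a, _ra, g_b, _rb in b.anchor_coords:
            key = (g_a, g_b)
            if key in estimates or (g_b, g_a) in estimates:
                continue
            if g_a not in cds:
                cds[g_a] = ga_genome.genes[g_a].cds
            if g_b not in cds:
                cds[g_b] = gb_genome.genes[g_b].cds
            estimates[key] = ks.pair_ks(cds[g_a], cds[g_b], g_a, g_b)
    return estimates


def run_pipeline(config: PipelineConfig,
                 genomes: list[AnnotatedGenome] | None = None) -> RunManifest:
    """Execute homology -> synteny -> Ks -> dating (-> topology test).

    ``genomes`` may be passed directly (e.g. fresh simulator output);
    otherwise they are read from the configured FASTA/GFF paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=VERSION, seed=config.seed)

    if genomes is None:
        genomes = [
            read_genome(g["fasta"], g["gff"], g["label"]) for g in config.genomes
        ]
    by_label = {g.label: g for g in genomes}
    labels = [g.label for g in genomes]

    @contextmanager
    def stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)
        try:
            yield
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        finally:
            manifest.timings[name] = round(time.time() - t0, 3)
            logger.info("stage %s finished in %.1fs", name, time.time() - t0)

    with stage("homology"):
        pairs = homology.find_homolog_pairs(
            genomes, min_identity=config.min_identity, top_n_hits=config.top_n_hits
        )
        homology.write_pair_table(pairs, out / "pairs.tsv")

    with stage("synteny"):
        all_blocks: list[synteny.CollinearBlock] = []
        bid = 0
        for i, la in enumerate(labels):
            for lb in labels[i:]:
                blocks = synteny.detect_blocks(
                    pairs, by_label[la], by_label[lb],
                    max_gap=config.max_gap, min_anchors=config.min_anchors,
                    match_score=config.match_score, gap_penalty=config.gap_penalty,
                    _id_start=bid,
                )
                bid += len(blocks)
                all_blocks.extend(blocks)
        synteny.write_block_table(all_blocks, out / "blocks.tsv")

    with stage("ks"):
        estimates = anchor_ks(all_blocks, by_label)
        ks.write_ks_table(estimates, out / "ks.tsv")
        ks.annotate_block_ks(all_blocks, estimates)
        synteny.write_block_table(all_blocks, out / "blocks_ks.tsv")
        synteny.write_dotplot_table(
            all_blocks, out / "dotplot.tsv",
            {k: v.ks for k, v in estimates.items() if v.ks is not None},
        )

    with stage("dating"):
        dists: list[dating.KsDistribution] = []
        for la in labels:
            vals = [b.median_ks for b in all_blocks
                    if b.genome_a == la and b.genome_b == la and b.median_ks is not None]
            if len(vals) >= dating.MIN_FIT_VALUES:
                dists.append(dating.KsDistribution(f"{la}-paralogs", vals, "paralog",
                                                   config.ks_max))
        cross_medians: dict[tuple[str, str], list[float]] = {}
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                vals = [b.median_ks for b in all_blocks
                        if {b.genome_a, b.genome_b} == {la, lb} and b.median_ks is not None]
                cross_medians[(la, lb)] = vals
                if len(vals) >= dating.MIN_FIT_VALUES:
                    dists.append(dating.KsDistribution(f"{la}-{lb}-orthologs", vals,
                                                       "ortholog", config.ks_max))
        for d in dists:
            dating.fit_peaks(d, max_components=config.max_components, seed=config.seed)
        if dists:
            table = dating.compare_distributions(dists)
            table.to_csv(out / "peaks.tsv", sep="\t", index=False)

        events: list[tuple[str, dating.WgdEvent]] = []
        calibration = None
        if config.calibration_divergence_time_my is not None:
            cal_ks = config.calibration_median_ks
            if cal_ks is None:
                # internal calibration: median of cross-genome block medians in
                # the orthologous (lowest-Ks) mixture component
                pair_key = (tuple(config.calibration_pair)
                            if config.calibration_pair else next(iter(cross_medians), None))
                vals = cross_medians.get(tuple(sorted(pair_key)), []) if pair_key else []
                if len(vals) >= dating.MIN_FIT_VALUES:
                    lo, hi = dating.orthologous_ks_window(
                        vals, seed=config.seed, max_components=config.max_components)
                    member_vals = [v for v in vals if lo <= v <= hi]
                    if member_vals:
                        cal_ks = float(median(member_vals))
            if cal_ks is not None:
                calibration = dating.calibrate_rate(
                    cal_ks, config.calibration_divergence_time_my)
                for d in dists:
                    if d.kind != "paralog" or not d.peaks:
                        continue
                    names = ["beta", "alpha"]  # younger (smaller Ks) first
                    for k_i, peak in enumerate(d.peaks):
                        name = names[k_i] if k_i < 2 else f"wgd{k_i + 1}"
                        age = dating.date_event(peak.location, calibration)
                        events.append((d.label, dating.WgdEvent(name, peak.location, age)))
        if events or calibration:
            lines = ["source\tevent\tpeak_ks\tage_my\tage_display\tr"]
            for src, ev in events:
                lines.append(f"{src}\t{ev.name}\t{ev.peak_ks:.4f}\t{ev.age_my:.2f}"
                             f"\t{ev.display_age}\t{calibration.r:.6e}")
            (out / "events.tsv").write_text("\n".join(lines) + "\n")
            manifest.summary["r"] = calibration.r
            manifest.summary["events"] = [
                {"source": src, "name": ev.name, "peak_ks": ev.peak_ks,
                 "age_my": ev.age_my, "age_display": ev.display_age}
                for src, ev in events
            ]

    if config.roles:
        with stage("phylo_test"):
            o, m, i_ = (config.roles["outgroup"], config.roles["mid"],
                        config.roles["ingroup"])
            groups = phylo.extract_anchor_groups(all_blocks, o, m, i_)
            cds_by_gene = {gid: by_label[lab].genes[gid].cds
                           for lab in (o, m, i_) for gid in by_label[lab].genes}
            calls = phylo.run_topology_test(groups, cds_by_gene)
            phylo.write_call_table(calls, out / "topology_calls.tsv")
            if calls:
                manifest.summary["topology_support"] = phylo.summarize_support(calls)
                (out / "topology_summary.txt").write_text(
                    json.dumps(manifest.summary["topology_support"], sort_keys=True) + "\n"
                )


    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.checksums[f.name] = _sha256(f)
    manifest.write(out / "manifest.json")
    return manifest
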