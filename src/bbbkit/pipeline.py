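"""End-to-end orchestration of the synthetic barrier-integrity pipeline.

A single YAML config (or :func:`demo_config`) drives all stages in
dependency order: synthetic input generation, then the barrier assay,
imaging, and transcriptome stages, then network ranking. One global seed
fans out to per-stage seeds through ``numpy.random.SeedSequence.spawn``,
so each stage is reproducible in isolation and the full report is
byte-identical for a given config and seed.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats as sps

from . import __version__
from .barrier_assay import compare_groups, permeability_total, teer_area
from .datatypes import AssayGeometry
from .junction_imaging import (esg_field_intensity, normalize_to_control,
                               project_stack, sample_junction_profiles,
                               subtract_background)
from .network_topology import CentralityConfig, rank_nodes
from .synthgen import (CountsGroundTruth, ImageGroundTruth, NetworkGroundTruth,
                       TranswellGroundTruth, gen_counts, gen_esg_stack,
                       gen_junction_stack, gen_network, gen_teer_readings,
                       gen_transwell_series)
from .transcriptome import (deletion_region_check, filter_degs, nb_de_test,
                            pca_samples, split_by_fold)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config", "students_t"]

_STAGES = ("assay", "imaging", "transcriptome", "network")


@dataclass
class PipelineConfig:
    """Pipeline-wide settings; per-stage parameter dicts override defaults."""

    seed: int = 0
    out_dir: str | None = None
    stages: tuple[str, ...] = _STAGES
    geometry: AssayGeometry = field(default_factory=AssayGeometry)
    # patient-vs-control setpoints for the synthetic demo
    n_pairs: int = 6
    teer_wt_net_ohm: float = 75.9     # -> 68.3 Ohm cm^2 on a 0.9 cm^2 insert
    teer_ratio: float = 0.62
    teer_noise_ohm: float = 3.0
    p_true_wt: float = 3.8e-6
    p_fold: float = 1.42
    p_noise_um: float = 0.005
    p_insert: float = 3.0e-5
    junction_deficit: float = 0.6
    esg_deficit: float = 0.42
    imaging_noise_frac: float = 0.05
    n_samples_imaging: int = 3
    fields_per_sample: int = 3
    fdr_max: float = 0.01
    base_mean_min: float = 100.0
    fold_up: float = 2.0
    fold_down: float = 0.5
    lambda_: float = 1.0
    counts: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        geom = AssayGeometry(**data.pop("geometry", {}))
        stages = tuple(data.pop("stages", _STAGES))
        return cls(geometry=geom, stages=stages, **data)

    def canonical(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items() if k != "geometry"}
        d["geometry"] = {k: getattr(self.geometry, k)
                         for k in vars(self.geometry)}
        return json.dumps(d, sort_keys=True, default=str)


def demo_config(seed: int = 0) -> PipelineConfig:
    """All-synthetic demo at the study's printed group setpoints."""
    return PipelineConfig(seed=seed)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic fan-out of one global seed into per-use seeds < 2^31."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1, dtype=np.uint32)[0] % (2 ** 31)) for c in children]


def students_t(a, b, paired: bool = False, welch: bool = False) -> tuple[float, float]:
    """Two-sided Student's t-test (paired, pooled two-sample, or Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if paired:
        d = a - b
        if np.var(d, ddof=1) == 0 and np.all(d == d[0]):
            if d[0] == 0:
                return 0.0, 1.0
            raise ValueError("zero variance of paired differences")
        t, p = sps.ttest_rel(a, b)
    else:
        if not welch and np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            raise ValueError("zero pooled variance with unequal means: t undefined")
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# stage runners


def _run_assay(cfg: PipelineConfig, seed: int) -> dict:
    seeds = _spawn_seeds(seed, 4 * cfg.n_pairs)
    geom = cfg.geometry
    teer_wt, teer_del, p_wt, p_del = [], [], [], []
    blank = 30.0
    for i in range(cfg.n_pairs):
        s0, s1, s2, s3 = seeds[4 * i: 4 * i + 4]
        for group, net_ohm, bucket, s in (
                ("WT", cfg.teer_wt_net_ohm, teer_wt, s0),
                ("DEL", cfg.teer_wt_net_ohm * cfg.teer_ratio, teer_del, s1)):
            readings = gen_teer_readings(net_ohm, blank, n=3,
                                         noise_sd_ohm=cfg.teer_noise_ohm, seed=s)
            net = (readings["total_ohm"] - readings["blank_ohm"]).mean()
            bucket.append(teer_area(net + blank, blank, geom.membrane_area_cm2).teer_ohm_cm2)
        for group, p_true, bucket, s in (
                ("WT", cfg.p_true_wt, p_wt, s2),
                ("DEL", cfg.p_true_wt * cfg.p_fold, p_del, s3)):
            series = gen_transwell_series(geom, TranswellGroundTruth(
                p_true_cm_s=p_true, noise_sd_um=cfg.p_noise_um, seed=s))
            bucket.append(permeability_total(series).p_total)
    return {
        "teer": compare_groups(teer_del, teer_wt),
        "permeability": compare_groups(p_del, p_wt),
        "p_insert": cfg.p_insert,
    }


def _run_imaging(cfg: PipelineConfig, seed: int) -> dict:
    n_stacks = 2 * cfg.n_samples_imaging * (1 + cfg.fields_per_sample)
    seeds = iter(_spawn_seeds(seed, n_stacks))
    amp, bg = 100.0, 10.0
    noise = cfg.imaging_noise_frac * amp

    junction_peaks = {"WT": [], "DEL": []}
    for group, deficit in (("WT", 1.0), ("DEL", cfg.junction_deficit)):
        for _ in range(cfg.n_samples_imaging):
            truth = ImageGroundTruth(junction_amplitude=amp, background_level=bg,
                                     deficit_factor=deficit, noise_sd=noise,
                                     seed=next(seeds))
            stack, segments = gen_junction_stack(truth)
            img = project_stack(stack)
            profs = sample_junction_profiles(img, segments, truth.pixel_size_um)
            profs = subtract_background(profs, img, segments)
            junction_peaks[group].append(float(profs.peaks.mean()))
    junction = normalize_to_control(junction_peaks["DEL"], junction_peaks["WT"])

    esg_stacks = {"WT": [], "DEL": []}
    for group, deficit in (("WT", 1.0), ("DEL", cfg.esg_deficit)):
        for _ in range(cfg.n_samples_imaging):
            fields = [gen_esg_stack(ImageGroundTruth(
                junction_amplitude=amp, background_level=0.0,
                deficit_factor=deficit, noise_sd=noise, seed=next(seeds),
                field_px=128, n_slices=3, pixel_size_um=0.5))
                for _ in range(cfg.fields_per_sample)]
            esg_stacks[group].append(fields)
    esg = esg_field_intensity(esg_stacks["WT"], esg_stacks["DEL"])
    return {
        "junction": {
            "del_normalized_mean": junction.del_mean,
            "del_percent_of_wt": junction.del_percent_of_wt,
            "wt_kurtosis": junction.wt_kurtosis,
            "del_kurtosis": junction.del_kurtosis,
        },
        "esg": {
            "del_normalized_mean": esg.del_mean,
            "del_percent_of_wt": esg.del_percent_of_wt,
            "wilcoxon_p": esg.wilcoxon_p,
        },
    }


def _run_transcriptome(cfg: PipelineConfig, seed: int) -> dict:
    params = {"deletion_gene_ids": tuple(f"DEL{i:03d}" for i in range(40)),
              **cfg.counts}
    cm = gen_counts(CountsGroundTruth(seed=seed, **params))
    table = nb_de_test(cm)
    degs = filter_degs(table, cfg.fdr_max, cfg.base_mean_min)
    split = split_by_fold(degs, cfg.fold_up, cfg.fold_down)
    check = deletion_region_check(degs, list(params["deletion_gene_ids"]))
    fractions, _scores = pca_samples(cm)
    return {
        "n_significant": int(len(degs)),
        "n_up": int(len(split.up)),
        "n_down": int(len(split.down)),
        "n_unsplit": int(len(split.unsplit)),
        "deletion_check": {
            "applicable": check.applicable,
            "fraction_down": check.fraction_down,
            "n_significant": check.n_significant,
        },
        "pc1_variance_fraction": float(fractions[0]),
    }


def _run_network(cfg: PipelineConfig, seed: int) -> dict:
    params = {"hub_id": "CRKL", **cfg.network}
    net = gen_network(NetworkGroundTruth(seed=seed, **params))
    ranking = rank_nodes(net, CentralityConfig(lambda_=cfg.lambda_),
                         measure="diffusion_degree")
    top_del = ranking.index[ranking["top_deletion"]]
    return {
        "measure": "diffusion_degree",
        "top_node": str(ranking.index[0]),
        "top_deletion_node": str(top_del[0]) if len(top_del) else None,
        "top_deletion_rank": int(ranking.loc[top_del[0], "rank"]) if len(top_del) else None,
        "n_nodes": int(len(ranking)),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages and return (and optionally write) the report."""
    stage_seeds = dict(zip(_STAGES, _spawn_seeds(cfg.seed, len(_STAGES))))
    runners = {"assay": _run_assay, "imaging": _run_imaging,
               "transcriptome": _run_transcriptome, "network": _run_network}
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(cfg.canonical().encode()).hexdigest(),
        "stages": {},
    }
    for stage in cfg.stages:
        if stage not in runners:
            raise ValueError(f"unknown stage: {stage}")
        try:
            report["stages"][stage] = runners[stage](cfg, stage_seeds[stage])
        except Exception as exc:
            raise RuntimeError(f"[{stage}] stage failed: {exc}") from exc
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        (out / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: dict) -> str:
    lines = [f"bbbkit {report['version']}  seed={report['seed']}",
             f"config {report['config_hash'][:12]}", ""]
    s = report["stages"]
    if "assay" in s:
        t, p = s["assay"]["teer"], s["assay"]["permeability"]
        lines += [
            f"TEER: DEL {t['del_mean']:.1f} vs WT {t['wt_mean']:.1f} Ohm.cm2 "
            f"({t['percent_of_wt']:.0f}% of WT, Wilcoxon p={t['wilcoxon_p']:.4g})",
            f"Permeability: DEL {p['del_mean']:.2e} vs WT {p['wt_mean']:.2e} cm/s "
            f"({p['fold_of_wt']:.1f}-fold, Wilcoxon p={p['wilcoxon_p']:.4g})",
        ]
    if "imaging" in s:
        lines += [
            f"Junction intensity: DEL {100 * s['imaging']['junction']['del_normalized_mean']:.0f}% of WT",
            f"Glycocalyx intensity: DEL {s['imaging']['esg']['del_percent_of_wt']:.0f}% of WT",
        ]
    if "transcriptome" in s:
        t = s["transcriptome"]
        lines += [
            f"DEGs: {t['n_significant']} significant "
            f"({t['n_up']} up FC>2, {t['n_down']} down FC<0.5); "
            f"deletion-region fraction down = {t['deletion_check']['fraction_down']}",
            f"PC1 variance fraction: {t['pc1_variance_fraction']:.2f}",
        ]
    if "network" in s:
        n = s["network"]
        lines += [f"Network: top deletion-region node by {n['measure']} = "
                  f"{n['top_deletion_node']} (rank {n['top_deletion_rank']})"]
    return "\n".join(lines) + "\n"
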