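"""End-to-end orchestration: registry -> cohort -> networks -> reports.

A run produces, per analyzed subgroup: the filtered cohort and filter
report, a GraphML + edge-list network, a statistics row, a resampling
comparison table (diagnosis subgroups only), two ERGM fits (step 1:
uniform occupation homophily; step 2: differential) with GOF summaries,
and a pruned-layout export.  A JSON manifest lists every artifact with
its SHA-256 hash and the configuration snapshot, so byte-identical
manifests certify reproducibility.

The master seed deterministically derives one independent child seed per
stage (registry, attribute resolution, resampling, ERGM GOF, layout), so
changing, say, the number of resampling iterations never perturbs the
network-construction randomness.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from psnet import cohort as _cohort
from psnet import ergm as _ergm
from psnet import io as _io
from psnet import metrics as _metrics
from psnet import network as _network
from psnet import resampling as _resampling
from psnet import synthetic as _synthetic
from psnet.errors import ConfigurationError

logger = logging.getLogger(__name__)

_STAGES = ("registry", "attributes", "resampling", "gof", "layout")
DIAGNOSIS_SUBGROUPS = ("substance", "psychosis", "depressive")


@dataclass
class RunConfig:
    input_path: str | None = None
    synthetic: _synthetic.SyntheticConfig | None = None
    subgroups: tuple[str, ...] = ("all",) + DIAGNOSIS_SUBGROUPS
    min_shared: int = 5
    keep_isolates: bool = True
    iterations: int = 100  # resampling M
    n_sim: int = 100  # GOF simulations
    ergm_steps: tuple[int, ...] = (1, 2)
    seed: int = 0
    out_dir: str = "psnet_run"

    def __post_init__(self) -> None:
        if self.min_shared < 1:
            raise ConfigurationError("min_shared must be >= 1")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        bad = set(self.subgroups) - {"all", *DIAGNOSIS_SUBGROUPS}
        if bad:
            raise ConfigurationError(f"unknown subgroup(s): {sorted(bad)}")
        if self.input_path is None and self.synthetic is None:
            self.synthetic = _synthetic.SyntheticConfig()

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            name: int(child.generate_state(1)[0])
            for name, child in zip(_STAGES, children)
        }

    def snapshot(self) -> dict:
        # out_dir excluded so manifests are byte-identical across locations
        d = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in ("synthetic", "out_dir")
        }
        d["subgroups"] = list(self.subgroups)
        d["ergm_steps"] = list(self.ergm_steps)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def _write_stats(stats: _metrics.NetworkStats, path: Path) -> None:
    row = {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in stats.to_row().items()}
    _io.write_json(row, path)


def _write_fit(fit: _ergm.ErgmFit, path: Path) -> None:
    frame = fit.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(frame.to_csv(sep="\t", index=False))
        fh.write(
            f"# loglik\t{fit.loglik:.6f}\n# AIC\t{fit.aic:.6f}\n"
            f"# BIC\t{fit.bic:.6f}\n# n_dyads\t{fit.n_dyads}\n"
            f"# converged\t{fit.converged}\n"
        )


def _write_gof(report: _ergm.GofReport, path: Path) -> None:
    payload = {
        "n_sim": report.n_sim,
        "fraction_inside": report.summary(),
        "panels": {
            name: {
                "bins": [str(b) for b in p.bins],
                "observed": p.observed,
                "sim_median": p.sim_median,
                "sim_lo": p.sim_lo,
                "sim_hi": p.sim_hi,
            }
            for name, p in report.panels.items()
        },
    }
    _io.write_json(payload, path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written)."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    artifacts: list[Path] = []

    # --- input registry ----------------------------------------------------
    if config.input_path is not None:
        visits = _io.read_visits(config.input_path)
    else:
        synth = dataclasses.replace(config.synthetic, seed=seeds["registry"])
        visits = _synthetic.generate_registry(synth)
        reg_path = out / "registry.tsv"
        _io.write_visits(visits, reg_path)
        synth.write_provenance(out / "registry.provenance.yaml")
        artifacts += [reg_path, out / "registry.provenance.yaml"]
    logger.info("registry: %d visits", len(visits))

    # --- cohort filtering --------------------------------------------------
    cohort_visits, report = _cohort.filter_cohort(visits)
    report.write(out / "filter_report.tsv")
    _io.write_visits(cohort_visits, out / "cohort.tsv")
    artifacts += [out / "filter_report.tsv", out / "cohort.tsv"]
    logger.info(
        "cohort: %d patients, %d visits",
        cohort_visits["patient_id"].nunique(),
        len(cohort_visits),
    )

    professionals = _network.resolve_attributes(cohort_visits, seed=seeds["attributes"])
    professionals.to_csv(out / "professionals.tsv", sep="\t", index=False)
    artifacts.append(out / "professionals.tsv")

    # --- per-subgroup analyses --------------------------------------------
    stats_by_group: dict[str, _metrics.NetworkStats] = {}
    nets: dict[str, object] = {}
    n_patients: dict[str, int] = {}
    for subgroup in config.subgroups:
        defn = _cohort.CohortDefinition(subgroup=subgroup)
        sub_visits = _cohort.extract_subgroup(cohort_visits, defn)
        n_patients[subgroup] = int(sub_visits["patient_id"].nunique())
        net = _network.build_sharing_network(
            sub_visits,
            min_shared=config.min_shared,
            keep_isolates=config.keep_isolates,
            professionals=professionals,
        )
        nets[subgroup] = net
        gpath = out / f"network_{subgroup}.graphml"
        epath = out / f"network_{subgroup}_edges.tsv"
        _network.write_network(net, gpath, epath)
        artifacts += [gpath, epath]
        stats = _metrics.network_summary(net)
        stats_by_group[subgroup] = stats
        spath = out / f"stats_{subgroup}.json"
        _write_stats(stats, spath)
        artifacts.append(spath)
        logger.info("network %s: %d nodes, %d edges", subgroup, stats.n_nodes, stats.n_edges)

        # ERGMs
        fits = []
        for step in config.ergm_steps:
            spec = _ergm.step1_spec() if step == 1 else _ergm.step2_spec()
            fit = _ergm.fit_ergm(net, spec)
            fpath = out / f"ergm_{subgroup}_step{step}.tsv"
            _write_fit(fit, fpath)
            artifacts.append(fpath)
            fits.append((step, fit))
        for step, fit in fits:
            if not fit.converged:
                continue
            gof_report = _ergm.gof(fit, net, n_sim=config.n_sim, seed=seeds["gof"])
            gpath2 = out / f"gof_{subgroup}_step{step}.json"
            _write_gof(gof_report, gpath2)
            artifacts.append(gpath2)

    # --- resampling comparisons -------------------------------------------
    if "all" in config.subgroups:
        for subgroup in config.subgroups:
            if subgroup == "all":
                continue
            nulls = _resampling.null_distribution(
                cohort_visits,
                professionals,
                n_patients=n_patients[subgroup],
                M=config.iterations,
                seed=seeds["resampling"],
                min_shared=config.min_shared,
                keep_isolates=config.keep_isolates,
            )
            table = _resampling.comparison_table(stats_by_group[subgroup], nulls)
            cpath = out / f"comparison_{subgroup}.tsv"
            table.to_csv(cpath, sep="\t", index=False)
            artifacts.append(cpath)

    # --- layout export -----------------------------------------------------
    for subgroup in config.subgroups:
        pruned = _network.prune_small_components(nets[subgroup], min_size=5)
        if pruned.number_of_nodes() == 0:
            continue
        layout = _network.export_layout(pruned, seed=seeds["layout"])
        lpath = out / f"layout_{subgroup}.tsv"
        layout.to_csv(lpath, sep="\t", index=False, float_format="%.6f")
        artifacts.append(lpath)

    manifest = {
        "config": config.snapshot(),
        "stage_seeds": seeds,
        "n_patients": n_patients,
        "artifacts": _io.hash_tree(artifacts, out),
    }
    _io.write_json(manifest, out / "manifest.json")
    logger.info("pipeline done in %.1fs", time.perf_counter() - t0)
    return manifest
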