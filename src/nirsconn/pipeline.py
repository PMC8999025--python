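"""Cohort-level orchestration: synthetic or file-based runs, table exports,
and demographic summaries.

``run_pipeline`` drives the full analysis for every configured group and
writes, per subject/session, oxy-Hb and connectivity TSVs, and per
group/session the mean connectivity, the thresholded binary network, the
edge-test table, the metric sweep, the small-world summary and the nodal
comparisons, plus a JSON manifest recording every parameter and seed needed
to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .errors import ConfigurationError, DataError, InconsistencyError, InvalidInputError
from .graph_metrics import DEFAULT_THRESHOLDS
from .model import PairedConnectivityModel
from .montage import load_default_montage
from .preprocess import DEFAULT_FS
from .synthetic import (
    DEFAULT_DURATION_S,
    NoiseSpec,
    PAPER_GROUP_SIZES,
    generate_paired_cohort,
    make_block_correlation,
)

log = logging.getLogger("nirsconn")

EXIT_OK, EXIT_CONFIG, EXIT_DATA, EXIT_NUMERICAL = 0, 2, 3, 4


@dataclass
class GroupSpec:
    """Synthesis parameters for one shift group."""

    label: str
    n_subjects: int
    within_r_pre: float = 0.8
    within_r_post: float = 0.6
    between_r: float = 0.3


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    input_mode: str = "synthetic"              # "synthetic" | "files"
    output_dir: str = "nirsconn_run"
    master_seed: int = 0
    # synthetic mode
    groups: list[GroupSpec] = field(default_factory=lambda: [
        GroupSpec("morning", PAPER_GROUP_SIZES["morning"]),
        GroupSpec("afternoon", PAPER_GROUP_SIZES["afternoon"]),
        GroupSpec("night", PAPER_GROUP_SIZES["night"], within_r_pre=0.6, within_r_post=0.8),
    ])
    duration_s: float = DEFAULT_DURATION_S
    fs_hz: float = DEFAULT_FS
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    # files mode: group label -> cohort manifest path
    cohort_manifests: dict[str, str] = field(default_factory=dict)
    # analysis
    threshold: float = 0.7
    sweep: tuple = DEFAULT_THRESHOLDS
    fdr_q: float = 0.05
    n_null: int = 100
    smallworld_T: float = 0.3

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"missing config file: {path}")
        with path.open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        groups = raw.pop("groups", None)
        noise = raw.pop("noise", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if groups is not None:
            cfg.groups = [GroupSpec(**g) for g in groups]
        if noise is not None:
            cfg.noise = NoiseSpec(**noise)
        if cfg.input_mode not in ("synthetic", "files"):
            raise ConfigurationError(f"unknown input_mode {cfg.input_mode!r}")
        return cfg

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["sweep"] = list(self.sweep)
        return d


def _load_group_subjects(cfg: RunConfig):
    """Yield (label, subjects) per group according to the input mode."""
    if cfg.input_mode == "files":
        if not cfg.cohort_manifests:
            raise ConfigurationError("files mode needs cohort_manifests")
        for label, manifest in cfg.cohort_manifests.items():
            mlabel, subjects = nio.read_cohort_tsv(manifest)
            yield label or mlabel, subjects
        return
    rng = np.random.default_rng(cfg.master_seed)
    for g in cfg.groups:
        truth_pre = make_block_correlation(g.within_r_pre, g.between_r)
        truth_post = make_block_correlation(g.within_r_post, g.between_r)
        cohort = generate_paired_cohort(
            g.n_subjects, truth_pre, truth_post, duration_s=cfg.duration_s,
            fs=cfg.fs_hz, noise=cfg.noise, seed=int(rng.integers(2**31 - 1)),
            group_label=g.label,
        )
        yield g.label, cohort.subjects


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every group end to end; returns a summary dict (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = load_default_montage()
    montage.to_brainnet_node(out / "montage.node")
    summary: dict = {"groups": {}}
    analysis_rng = np.random.default_rng(cfg.master_seed + 1)
    log_lines: list[str] = []

    for label, subjects in _load_group_subjects(cfg):
        t0 = time.perf_counter()
        gdir = out / label
        gdir.mkdir(exist_ok=True)
        try:
            pre = [s[0] for s in subjects]
            post = [s[1] for s in subjects]
            model = PairedConnectivityModel(pre, post, montage=montage,
                                            group_label=label, apply_bandpass=True)
            res = model.fit(r_threshold=cfg.threshold, fdr_q=cfg.fdr_q,
                            thresholds=cfg.sweep, n_null=cfg.n_null,
                            smallworld_T=cfg.smallworld_T,
                            seed=int(analysis_rng.integers(2**31 - 1)))
        except Exception:
            (gdir / "FAILED").write_text(f"stage failure in group {label}\n")
            log.exception("group %s failed", label)
            raise

        # per-subject artifacts
        for sess, series, mats in (("pre", pre, res.cor_pre), ("post", post, res.cor_post)):
            for hb, mat in zip(series, mats):
                sid = hb.subject_id or "subject"
                nio.write_hb_tsv(hb, gdir / f"{sid}_{sess}_hb.tsv")
                nio.write_cor_tsv(mat, gdir / f"{sid}_{sess}_cor.tsv")

        # group-level artifacts
        nio.write_cor_tsv(res.group_mean_pre, gdir / "group_mean_cor_pre.tsv")
        nio.write_cor_tsv(res.group_mean_post, gdir / "group_mean_cor_post.tsv")
        nio.write_brainnet_edge(res.network_pre, gdir / "network_pre.edge")
        nio.write_brainnet_edge(res.network_post, gdir / "network_post.edge")
        res.edge_frame().to_csv(gdir / "edge_tests.tsv", sep="\t", index=False,
                                float_format="%.10g")
        sweep_rows = []
        for sess, profs in (("pre", res.profiles_pre), ("post", res.profiles_post)):
            for prof in profs:
                df = prof.to_frame()
                df.insert(0, "session", sess)
                df.insert(0, "subject_id", prof.subject_id)
                sweep_rows.append(df)
        pd.concat(sweep_rows).to_csv(gdir / "metric_sweep.tsv", sep="\t",
                                     index=False, float_format="%.10g")
        sw = pd.DataFrame([
            {"session": "pre", **_sw_row(res.smallworld_pre)},
            {"session": "post", **_sw_row(res.smallworld_post)},
        ])
        sw.to_csv(gdir / "small_world.tsv", sep="\t", index=False, float_format="%.10g")
        res.nodal_bc.to_csv(gdir / "nodal_betweenness.tsv", sep="\t", index=False,
                            float_format="%.10g")
        res.nodal_eloc.to_csv(gdir / "nodal_local_efficiency.tsv", sep="\t", index=False,
                              float_format="%.10g")
        (gdir / "summary.txt").write_text(res.summary() + "\n")

        elapsed = time.perf_counter() - t0
        log.info("group %s done in %.1f s", label, elapsed)
        log_lines.append(f"group {label}: n={len(pre)} seed-echo master_seed={cfg.master_seed} "
                         f"elapsed={elapsed:.2f}s degenerate_edges="
                         f"{int(res.edge_result.degenerate.sum())}")
        summary["groups"][label] = {
            "n_subjects": len(pre),
            "mean_cor_pre": float(res.mean_cor_pre.mean()),
            "mean_cor_post": float(res.mean_cor_post.mean()),
            "mean_cor_t": res.mean_cor_t,
            "mean_cor_p": res.mean_cor_p,
            "n_significant_edges": res.n_significant_edges,
            "sigma_pre": res.smallworld_pre.sigma,
            "sigma_post": res.smallworld_post.sigma,
        }

    manifest = {"config": cfg.to_manifest(), "results": summary}
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _sw_row(sw) -> dict:
    return {"gamma": sw.gamma, "lambda": sw.lambda_, "sigma": sw.sigma,
            "Cnet": sw.Cnet, "Lnet": sw.Lnet, "Cran": sw.Cran, "Lran": sw.Lran,
            "n_null": sw.n_null}


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------

@dataclass
class DemographicTable:
    """Counts per category, per group and overall.

    ``counts`` maps section -> category -> list of counts aligned with
    ``groups`` (first entry is the overall cohort).
    """

    groups: list[str]
    n: list[int]
    counts: dict[str, dict[str, list[int]]]

    def __post_init__(self) -> None:
        for section, cats in self.counts.items():
            for cat, row in cats.items():
                if len(row) != len(self.groups):
                    raise InvalidInputError(f"{section}/{cat}: wrong number of columns")
                if any(c < 0 for c in row):
                    raise InvalidInputError(f"{section}/{cat}: negative count")
                if sum(row[1:]) != row[0]:
                    raise InconsistencyError(
                        f"{section}/{cat}: group counts {row[1:]} do not sum to overall {row[0]}"
                    )


def load_default_demographics() -> DemographicTable:
    """Packaged head counts of the 54-worker three-shift cohort."""
    with resources.files("nirsconn.data").joinpath("demographics.json").open() as fh:
        raw = json.load(fh)
    return DemographicTable(groups=raw["groups"], n=raw["n"], counts=raw["categories"])


def percentage(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to one decimal."""
    if total <= 0:
        raise InvalidInputError("total must be positive")
    if not 0 <= count <= total:
        raise InvalidInputError("count must satisfy 0 <= count <= total")
    return float((Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


def demographic_summary(table: DemographicTable | None = None) -> pd.DataFrame:
    """Per-category counts and percentages, overall and per group."""
    if table is None:
        table = load_default_demographics()
    rows = []
    for section, cats in table.counts.items():
        for cat, row in cats.items():
            entry = {"section": section, "category": cat}
            for grp, n_grp, count in zip(table.groups, table.n, row):
                entry[f"{grp}_n"] = count
                entry[f"{grp}_pct"] = percentage(count, n_grp)
            rows.append(entry)
    return pd.DataFrame(rows)
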