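"""End-to-end seeded runs: simulate -> features -> labels -> decode -> test.

A run is a pure function of its :class:`RunConfig`: every stage draws
its randomness from a seed derived by hashing (run seed, stage name), so
re-running a config reproduces all numeric outputs exactly.  The run
writes the intermediate artifacts (behaviour CSV, feature CSV, label
CSVs), a machine-readable ``summary.json``, and, on request, the two
result figures: the ROC curve of the slow-vs-fast task and the 5x5
pairwise AUC matrix with significance stars.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .decode import crossval_auc
from .inference import (
    pairwise_task_aucs,
    shift_null_distribution,
    significance_report,
    speed_gap_correlation,
)
from .labeling import discretize_bins, extreme_decile_labels
from .preprocess import extract_features
from .simulate import SimConfig, generate_session

__all__ = [
    "PipelineError",
    "RunConfig",
    "derive_stage_seed",
    "load_run_config",
    "save_run_config",
    "run_pipeline",
    "render_report",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Nested configuration of a full decoding run."""

    sim: SimConfig = field(default_factory=SimConfig)
    scheme: str = "both"  # "decile" | "bins" | "both"
    fraction: float = 0.10
    bin_width: float = 10.0
    k: int = 10
    n_perm: int = 1000
    min_shift: int = 20
    alpha: float = 0.05
    two_sided: bool = False
    folds: str = "stratified"  # or "contiguous" (temporally blocked CV)
    seed: int = 7
    outdir: str = "hipponav_run"
    save_session: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in ("decile", "bins", "both"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.folds not in ("stratified", "contiguous"):
            raise ValueError(f"unknown fold policy {self.folds!r}")


def derive_stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the run seed and stage name."""
    digest = hashlib.blake2s(f"{run_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("sim", {})
    sim_raw.setdefault("seed", 0)
    for key in ("f_theta_range", "f_gamma_range"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    return RunConfig(sim=SimConfig(**sim_raw), **raw)


def save_run_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    d = dataclasses.asdict(config)
    d["sim"] = dataclasses.asdict(config.sim)
    for key in ("f_theta_range", "f_gamma_range"):
        d["sim"][key] = list(d["sim"][key])
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
        return out

    return wrap


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer, np.bool_)):
        return x.item()
    return x


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full seeded run and write its artifacts to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_seed = derive_stage_seed(config.seed, "simulate")
    cv_seed = derive_stage_seed(config.seed, "crossval")
    perm_seed = derive_stage_seed(config.seed, "permtest")

    sim_cfg = config.sim.with_(seed=sim_seed)
    session, trace = _stage("simulate")(generate_session, sim_cfg)
    hio.write_behavior(trace, outdir / "behavior.csv")
    if config.save_session:
        hio.write_session(session, outdir / "session", seed=sim_seed,
                          config=sim_cfg)

    table = _stage("features")(extract_features, session, trace)
    hio.write_feature_table(table, outdir / "features.csv")

    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=_jsonable)),
        "stage_seeds": {"simulate": sim_seed, "crossval": cv_seed,
                        "permtest": perm_seed},
        "n_windows": table.n_windows,
    }

    if config.scheme in ("decile", "both"):
        ds = _stage("label_decile")(extreme_decile_labels, table, config.fraction)
        _write_labels(ds, outdir / "labels_decile.csv")
        res = _stage("decode_decile")(crossval_auc, ds, config.k, cv_seed,
                                      config.folds)
        null = _stage("permtest_decile")(
            shift_null_distribution, table, "decile", config.n_perm,
            config.min_shift, perm_seed, config.fraction, config.bin_width,
            config.sim.v_max, config.k, cv_seed, config.folds,
        )
        rep = significance_report(np.array([res.auc]), null,
                                  alpha=config.alpha, two_sided=config.two_sided)
        summary["decile"] = {
            "auc": res.auc,
            "n_per_class": int(ds.n_samples // 2),
            "k": res.k,
            "p_raw": float(rep.p_raw[0]),
            "p_adjusted": float(rep.p_adjusted[0]),
            "significant": bool(rep.significant[0]),
            "n_perm": rep.n_perm,
            "roc_points": np.asarray(res.roc_points).tolist(),
        }

    if config.scheme in ("bins", "both"):
        binned = _stage("label_bins")(discretize_bins, table,
                                      config.bin_width, config.sim.v_max)
        _write_labels(binned, outdir / "labels_bins.csv")
        tasks, aucs = _stage("decode_bins")(
            pairwise_task_aucs, table, config.bin_width, config.sim.v_max,
            config.k, cv_seed, config.folds,
        )
        null = _stage("permtest_bins")(
            shift_null_distribution, table, "bins", config.n_perm,
            config.min_shift, perm_seed, config.fraction, config.bin_width,
            config.sim.v_max, config.k, cv_seed, config.folds,
        )
        rep = significance_report(aucs, null, alpha=config.alpha,
                                  two_sided=config.two_sided)
        entries = []
        for j, t in enumerate(tasks):
            entries.append({
                "bin_lo": t.bin_lo,
                "bin_hi": t.bin_hi,
                "gap": t.gap,
                "auc": float(aucs[j]),
                "p_raw": float(rep.p_raw[j]),
                "p_adjusted": float(rep.p_adjusted[j]),
                "significant": bool(rep.significant[j]),
            })
        bins_summary: dict = {
            "tasks": entries,
            "n_perm": rep.n_perm,
            "n_significant": int(rep.significant.sum()),
        }
        if len(tasks) >= 3:
            r, p = speed_gap_correlation(tasks, aucs)
            bins_summary["gap_auc_correlation"] = {"r": r, "p": p}
        summary["bins"] = bins_summary

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )
    return summary


def _write_labels(ds, path: Path) -> None:
    lines = ["window_index,label"]
    for i, lab in zip(ds.window_index, ds.labels):
        lines.append(f"{int(i)},{int(lab)}")
    path.write_text("\n".join(lines) + "\n")


def render_report(summary: dict, outdir: str | Path) -> list[Path]:
    """Render the ROC curve and the pairwise AUC matrix from a summary.

    Produces deterministic file names: ``report_roc.png`` +
    ``roc_points.csv`` for the decile task, ``report_auc_matrix.png`` +
    ``auc_matrix.csv`` for the pairwise tasks.  Significant matrix cells
    carry an asterisk.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "decile" not in summary and "bins" not in summary:
        raise ValueError("summary holds no results to render")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "decile" in summary:
        pts = np.asarray(summary["decile"]["roc_points"], dtype=float)
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(pts[:, 0], pts[:, 1], lw=1.5)
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title("Slow vs fast extreme-decile speeds")
        ax.text(0.95, 0.05, f"AUC = {summary['decile']['auc']:.3f}",
                ha="right", va="bottom", transform=ax.transAxes)
        fig.tight_layout()
        p = outdir / "report_roc.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        csv_p = outdir / "roc_points.csv"
        lines = ["fpr,tpr"] + [f"{a:.17g},{b:.17g}" for a, b in pts]
        csv_p.write_text("\n".join(lines) + "\n")
        written.append(csv_p)

    if "bins" in summary:
        tasks = summary["bins"]["tasks"]
        n_bins = max(t["bin_hi"] for t in tasks) + 1 if tasks else 0
        mat = np.full((n_bins, n_bins), np.nan)
        sig = np.zeros((n_bins, n_bins), dtype=bool)
        for t in tasks:
            mat[t["bin_lo"], t["bin_hi"]] = t["auc"]
            sig[t["bin_lo"], t["bin_hi"]] = t["significant"]
        fig, ax = plt.subplots(figsize=(5.2, 4.6))
        masked = np.ma.masked_invalid(mat)
        im = ax.imshow(masked, vmin=0.5, vmax=1.0, cmap="viridis")
        for t in tasks:
            star = "*" if t["significant"] else ""
            ax.text(t["bin_hi"], t["bin_lo"], f"{t['auc']:.2f}{star}",
                    ha="center", va="center", fontsize=8,
                    color="white" if t["auc"] < 0.85 else "black")
        ticks = [f"{10 * i:g}–{10 * (i + 1):g}" for i in range(n_bins)]
        ax.set_xticks(range(n_bins), ticks)
        ax.set_yticks(range(n_bins), ticks)
        ax.set_xlabel("speed bin (units/s)")
        ax.set_ylabel("speed bin (units/s)")
        ax.set_title("Pairwise speed-bin AUC (* = maxT significant)")
        fig.colorbar(im, ax=ax, label="AUC")
        fig.tight_layout()
        p = outdir / "report_auc_matrix.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        csv_p = outdir / "auc_matrix.csv"
        lines = ["bin_lo,bin_hi,gap,auc,p_adjusted,significant"]
        for t in tasks:
            lines.append(
                f"{t['bin_lo']},{t['bin_hi']},{t['gap']:.17g},"
                f"{t['auc']:.17g},{t['p_adjusted']:.17g},{int(t['significant'])}"
            )
        csv_p.write_text("\n".join(lines) + "\n")
        written.append(csv_p)

    return written
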