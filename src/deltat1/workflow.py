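"""End-to-end run: simulate a cohort, push every subject through the imaging
chain, and compute the study-style summary and group statistics.

The stages are: cohort simulation -> phantom -> pre/post MP2RAGE forward
acquisition -> T1-map reconstruction -> (optional) rigid registration ->
ΔT1 subtraction -> per-subject ROI metrics -> group statistics -> report.
A run is fully determined by its configuration and seed; outputs carry a
provenance header with the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .cohort import CohortSpec, SubjectRecord, cohort_table, simulate_cohort
from .exceptions import ConfigurationError, DeltaT1Error, EmptyRoiError
from .lookup import build_lookup
from .phantom import (
    PhantomConfig,
    apply_gadolinium,
    build_phantom,
    simulate_acquisition,
)
from .pipeline import compute_delta_t1, reconstruct_t1_map, register_post_to_pre
from .protocol import SequenceProtocol
from .roi import roi_metrics
from .stats import (
    StatResult,
    compare_groups,
    compare_paired,
    correlate,
    dichotomize_by_median,
    fdr_adjust,
    fit_treatment_logistic,
)

__all__ = ["RunConfig", "run_end_to_end", "group_statistics", "write_report"]

logger = logging.getLogger("deltat1")

_TISSUES = ("nel", "el", "nawm", "cgm")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str
    seed: int = 0
    n_subjects: int = 3
    shape: tuple[int, int, int] = (48, 48, 48)
    lesion_count: int = 3
    el_fraction: float = 0.0
    noise_sigma: float = 0.0
    misalignment: tuple[float, float, float, float, float, float] | None = None
    registration: str = "none"  # none | known | estimate
    pms_fraction: float = 13 / 47
    protocol: SequenceProtocol = field(default_factory=SequenceProtocol)
    write_volumes: bool = True
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.registration not in ("none", "known", "estimate"):
            raise ConfigurationError("registration must be none, known, or estimate")
        if self.misalignment is not None and self.registration == "none":
            raise ConfigurationError(
                "a misalignment is configured but registration is disabled"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        protocol_path = raw.pop("protocol_file", None)
        raw.update(overrides)
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        if raw.get("misalignment") is not None:
            raw["misalignment"] = tuple(raw["misalignment"])
        if protocol_path is not None and "protocol" not in raw:
            raw["protocol"] = SequenceProtocol.from_file(protocol_path)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        # Only the scientific configuration: where outputs land and how
        # chatty the run is must not change the provenance identity.
        for bookkeeping in ("out_dir", "verbosity", "write_volumes"):
            payload.pop(bookkeeping)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _process_subject(
    record: SubjectRecord,
    base_config: PhantomConfig,
    tissues,
    run: RunConfig,
    table,
    out_subj: Path | None,
    provenance: dict,
) -> tuple[list[dict], dict]:
    config = dataclasses.replace(
        base_config,
        shape=run.shape,
        lesion_count=run.lesion_count,
        el_fraction=run.el_fraction,
        noise_sigma=run.noise_sigma,
        misalignment=run.misalignment,
    )
    gt = apply_gadolinium(build_phantom(config, tissues))
    inv2_pre, uni_pre = simulate_acquisition(gt, run.protocol, config, phase="pre")
    inv2_post, uni_post = simulate_acquisition(gt, run.protocol, config, phase="post")

    rec_pre = reconstruct_t1_map(inv2_pre, uni_pre, run.protocol, table)
    transform = None
    if run.registration == "known" and config.misalignment is not None:
        reg, [uni_post] = register_post_to_pre(
            inv2_post, inv2_pre, mode="known_transform",
            known_transform=gt.applied_misalignment, extra=[uni_post],
        )
        inv2_post, transform = reg.aligned, reg.transform
    elif run.registration == "estimate":
        reg, [uni_post] = register_post_to_pre(
            inv2_post, inv2_pre, mode="estimate_rigid", extra=[uni_post]
        )
        inv2_post, transform = reg.aligned, reg.transform
    rec_post = reconstruct_t1_map(inv2_post, uni_post, run.protocol, table)
    delta = compute_delta_t1(
        rec_pre.t1, rec_post.t1, rec_pre.qc_exclude, rec_post.qc_exclude,
        provenance={"subject": record.subject_id},
    )

    rows = []
    maps = {"pre": rec_pre.t1, "post": rec_post.t1, "delta": delta}
    for tissue in _TISSUES:
        mask = gt.masks[tissue]
        for phase, map_like in maps.items():
            try:
                metrics = roi_metrics(
                    map_like, mask, subject_id=record.subject_id, tissue=tissue
                )
            except EmptyRoiError:
                continue  # e.g. no enhancing lesions in this subject
            row = metrics.as_dict()
            row["phase"] = phase
            rows.append(row)

    if out_subj is not None:
        out_subj.mkdir(parents=True, exist_ok=True)
        dio.write_volume(rec_pre.t1, out_subj / "t1_pre.nii.gz", provenance)
        dio.write_volume(rec_post.t1, out_subj / "t1_post.nii.gz", provenance)
        dio.write_volume(delta.as_volume(), out_subj / "delta_t1.nii.gz", provenance)
        for name, mask in gt.masks.as_dict().items():
            dio.write_mask(mask, gt.affine, out_subj / f"mask_{name}.nii.gz", provenance)
        if transform is not None:
            dio.write_transform(transform, gt.affine, out_subj / "post_to_pre.txt")
    summary = {"subject_id": record.subject_id}
    return rows, summary


def group_statistics(metrics: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """The study's statistical battery on the per-subject metric table.

    ``metrics`` is the ROI-metrics table (one row per subject x tissue x
    phase) and ``covariates`` the per-subject clinical table; this is the
    tabular contract between the imaging and statistics halves, also used
    by the ``delta-t1 stats`` subcommand on files.
    """
    rows: list[dict] = []

    def add(comparison: str, tissue: str, metric: str, res: StatResult) -> None:
        rows.append(
            {
                "comparison": comparison,
                "tissue": tissue,
                "metric": metric,
                "estimate": res.estimate,
                "p_value": res.p_value,
                "method": res.method,
                "n": res.n,
                "flagged": res.flagged,
            }
        )

    med = metrics.pivot_table(
        index="subject_id", columns=["tissue", "phase"], values="median"
    )
    # Paired pre/post on per-subject medians, per tissue.
    for tissue in _TISSUES:
        if (tissue, "pre") not in med.columns or (tissue, "post") not in med.columns:
            continue
        pair = med[[(tissue, "pre"), (tissue, "post")]].dropna()
        if len(pair) < 3:
            continue
        t_res, w_res = compare_paired(pair[(tissue, "pre")], pair[(tissue, "post")])
        add("pre_vs_post", tissue, "median_t1", t_res)
        add("pre_vs_post", tissue, "median_t1", w_res)

    nel = metrics.query("tissue == 'nel' and phase == 'delta'").set_index("subject_id")
    if len(nel) >= 4:
        joined = nel.join(covariates, how="inner", rsuffix="_cov")
        for metric in ("median", "mean", "variance", "iqr", "kurtosis"):
            values = joined[metric].to_numpy(float)
            ok = np.isfinite(values)
            # Group comparisons on the NEL delta metric.
            for comparison, split in (
                ("pms_vs_rrms", joined["phenotype"].eq("PMS").to_numpy()),
                ("untreated_vs_treated", ~joined["treated"].to_numpy(bool)),
                (
                    "edss_above_vs_below_median",
                    joined["edss"].to_numpy(float) > np.median(joined["edss"]),
                ),
            ):
                a, b = values[split & ok], values[~split & ok]
                if len(a) >= 2 and len(b) >= 2:
                    add(comparison, "nel", metric, compare_groups(a, b))
            # Correlation with disability.
            edss = joined["edss"].to_numpy(float)
            if ok.sum() >= 4:
                add(
                    "corr_edss",
                    "nel",
                    metric,
                    correlate(values[ok], edss[ok], method="spearman"),
                )
        # Logistic treatment model, adjusted for phenotype.
        treated = joined["treated"].to_numpy(bool).astype(float)
        if len(np.unique(treated)) == 2:
            pheno = joined["phenotype"].eq("PMS").to_numpy(float)
            fit = fit_treatment_logistic(
                joined["median"].to_numpy(float), treated, pheno
            )
            rows.append(
                {
                    "comparison": "treatment_logistic",
                    "tissue": "nel",
                    "metric": "median",
                    "estimate": fit.beta1,
                    "p_value": fit.p1,
                    "method": "logistic (phenotype-adjusted)",
                    "n": len(joined),
                    "flagged": fit.flagged,
                }
            )

    stats = pd.DataFrame(rows)
    if not stats.empty:
        stats["p_adjusted"] = np.nan
        corr = stats["comparison"].str.startswith("corr_") & stats["p_value"].notna()
        if corr.any():
            stats.loc[corr, "p_adjusted"] = fdr_adjust(stats.loc[corr, "p_value"])
    return stats


def write_report(
    metrics: pd.DataFrame, stats: pd.DataFrame, records: list[SubjectRecord]
) -> str:
    """Human-readable summary: tissue T1 table plus group comparisons.

    The tissue table reports the cohort median (range) of the per-subject
    median pre-contrast T1, post-contrast T1, and ΔT1, per tissue; group
    rows mirror the Mann-Whitney comparisons on NEL ΔT1 metrics.
    """
    lines = []
    n = len(records)
    n_pms = sum(r.phenotype == "PMS" for r in records)
    lines.append(f"Cohort: {n} subjects ({n - n_pms} RRMS, {n_pms} PMS)")
    n_treated = sum(r.treated for r in records)
    lines.append(f"On treatment: {n_treated} ({100 * n_treated / n:.1f}%)")
    lines.append("")
    lines.append("Per-tissue T1 metrics: median (range) of per-subject medians [s]")
    header = f"{'tissue':8s} {'pre-contrast T1':>22s} {'post-contrast T1':>22s} {'delta T1':>22s}"
    lines.append(header)

    def fmt(series: pd.Series) -> str:
        if series.empty:
            return "n/a"
        return f"{series.median():.3f} ({series.min():.3f}, {series.max():.3f})"

    for tissue in _TISSUES:
        sub = metrics[metrics["tissue"] == tissue]
        if sub.empty:
            lines.append(f"{tissue:8s} {'n/a':>22s} {'n/a':>22s} {'n/a':>22s}")
            continue
        cells = [
            fmt(sub.loc[sub["phase"] == phase, "median"])
            for phase in ("pre", "post", "delta")
        ]
        lines.append(
            f"{tissue:8s} {cells[0]:>22s} {cells[1]:>22s} {cells[2]:>22s}"
        )
    lines.append("")
    if not stats.empty:
        lines.append("Group comparisons and correlations (NEL delta-T1 metrics)")
        for _, row in stats.iterrows():
            p = "flagged" if row.get("flagged") else f"p={row['p_value']:.4g}"
            adj = row.get("p_adjusted")
            adj_txt = f", adj p={adj:.4g}" if pd.notna(adj) else ""
            lines.append(
                f"  {row['comparison']:28s} {row['tissue']:5s} {row['metric']:10s} "
                f"estimate={row['estimate']:+.4g} {p}{adj_txt} [{row['method']}]"
            )
    return "\n".join(lines) + "\n"


def run_end_to_end(run: RunConfig) -> dict:
    """Execute the whole chain and write the report bundle.

    Returns a dict with the metric table, covariate table, statistics table,
    report text, and output paths.  Deterministic for a fixed configuration
    and seed.  On a stage failure, partial outputs are retained next to a
    ``FAILED`` marker file and the error re-raised.
    """
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    level = logging.WARNING if run.verbosity == 0 else logging.INFO
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
    log_file = logging.FileHandler(out / "run.log")
    log_file.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(log_file)

    provenance = {"seed": run.seed, "config": run.config_hash()}
    started = time.time()
    try:
        spec = CohortSpec(n_subjects=run.n_subjects, pms_fraction=run.pms_fraction, seed=run.seed)
        records, configs = simulate_cohort(spec)
        covariates = cohort_table(records)
        table = build_lookup(run.protocol)

        all_rows: list[dict] = []
        for record in records:
            t0 = time.time()
            base_config, tissues = configs[record.subject_id]
            out_subj = out / record.subject_id if run.write_volumes else None
            rows, _ = _process_subject(
                record, base_config, tissues, run, table, out_subj, provenance
            )
            all_rows.extend(rows)
            logger.info(
                "subject %s done in %.1fs", record.subject_id, time.time() - t0
            )
        metrics = pd.DataFrame(all_rows)
        stats = group_statistics(metrics, covariates)
        report = write_report(metrics, stats, records)

        dio.write_table(metrics, out / "roi_metrics.csv", provenance)
        dio.write_table(covariates, out / "covariates.csv", provenance)
        if not stats.empty:
            dio.write_table(stats, out / "group_stats.csv", provenance)
        (out / "report.txt").write_text(report)
        (out / "provenance.json").write_text(
            json.dumps(
                {
                    "seed": run.seed,
                    "config_hash": run.config_hash(),
                    "config": dataclasses.asdict(run),
                    "n_subjects": len(records),
                    "python": sys.version.split()[0],
                    "numpy": np.__version__,
                },
                indent=2,
                default=str,
            )
        )
        logger.info("run complete in %.1fs", time.time() - started)
        return {
            "metrics": metrics,
            "covariates": covariates,
            "stats": stats,
            "report": report,
            "out_dir": str(out),
        }
    except DeltaT1Error:
        (out / "FAILED").write_text("run failed; partial outputs retained\n")
        raise
    finally:
        logger.removeHandler(log_file)
        log_file.close()
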