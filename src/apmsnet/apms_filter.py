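"""High-confidence interactor calling from AP-MS LFQ matrices.

The filter runs five steps, in this order:

(i)   drop proteins flagged "only identified by site", "potential
      contaminant" or "reverse";
(ii)  turn literal-0 observations into missing values;
(iii) remove outlier runs (few observed proteins, or low overall
      intensity relative to the cohort);
(iv)  keep a protein for a condition group only if observed in >= 60% of
      the group's remaining runs (a group is the 3 biological x 2
      technical replicates of one condition, plus the bead-control group);
(v)   test each condition against the bead-only control with a moderated
      t after mixed imputation (kNN for MAR cells, a below-detection floor
      for MNAR cells), adjust per condition with Benjamini-Hochberg, and
      call interactors at p_adj < 0.01 and log2 fold change > 1.

Technical replicates are then merged per biological replicate using the
median over observed values.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import stats_core
from .datasets import Condition, LFQDataset, condition_label

CONTROL_GROUP = "control"


@dataclasses.dataclass
class FilterParams:
    """Tunable knobs of the five-step filter."""

    min_proteins: int | None = None  # None -> 50% of the cohort median count
    mad_k: float = 3.0
    presence_frac: float = 0.6
    strategy_mar: str = "knn"
    strategy_mnar: str = "zero_floor"
    knn_k: int = 10
    p_adj_cutoff: float = 0.01
    logfc_cutoff: float = 1.0
    seed: int = 0


@dataclasses.dataclass
class FilterReport:
    """Before/after accounting for every filter step."""

    steps: list[dict] = dataclasses.field(default_factory=list)
    removed_runs: list[str] = dataclasses.field(default_factory=list)
    skipped_conditions: list[str] = dataclasses.field(default_factory=list)
    group_sizes: dict = dataclasses.field(default_factory=dict)

    def record(self, step: str, ds: LFQDataset) -> None:
        self.steps.append(
            {
                "step": step,
                "n_proteins": ds.intensity.shape[0],
                "n_runs": ds.intensity.shape[1],
                "n_observations": int(
                    ds.intensity.notna().to_numpy().sum()
                    if ds.intensity.isna().any().any()
                    else (ds.intensity.to_numpy() > 0).sum()
                ),
            }
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


@dataclasses.dataclass
class FilterResult:
    dataset: LFQDataset  # log2, technical replicates merged
    calls: dict  # Condition -> DataFrame of interactor calls
    report: FilterReport
    presence: pd.DataFrame  # proteins x groups boolean


# --------------------------------------------------------------------- #
# the five steps
# --------------------------------------------------------------------- #
def remove_flagged(ds: LFQDataset) -> LFQDataset:
    """Step (i): drop proteins with any identification flag set."""
    flags = ds.proteins[["flag_site_only", "flag_contaminant", "flag_reverse"]]
    keep = ~flags.any(axis=1)
    if not keep.any():
        warnings.warn("all proteins flagged; dataset is empty", stacklevel=2)
    return ds.subset(proteins=ds.proteins.index[keep])


def drop_zero_observations(ds: LFQDataset) -> LFQDataset:
    """Step (ii): literal 0 becomes missing; matrix shape is unchanged."""
    out = ds.copy()
    out.intensity = out.intensity.mask(out.intensity == 0.0)
    return out


def detect_outlier_runs(
    ds: LFQDataset, min_proteins: int | None = None, mad_k: float = 3.0
) -> list[str]:
    """Step (iii): flag runs with few observed proteins or low intensity.

    A run is flagged iff its observed-protein count is below
    ``min_proteins`` (default: half the cohort median count) or its median
    log2 intensity is more than ``mad_k`` MADs below the cohort median of
    run medians.  Raises if every run would be flagged.
    """
    obs_counts = ds.intensity.notna().sum(axis=0)
    if min_proteins is None:
        min_proteins = int(np.floor(0.5 * float(obs_counts.median())))
    vals = ds.intensity.to_numpy(dtype=float)
    logged = vals if ds.log2_scale else np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        run_medians = np.nanmedian(logged, axis=0)
    global_med = np.nanmedian(run_medians)
    mad = np.nanmedian(np.abs(run_medians - global_med))
    # 1.4826 makes the MAD a consistent sigma estimate; the 0.1-log2 floor
    # keeps near-identical cohorts from flagging trivial fluctuations
    scale = max(1.4826 * mad, 0.1)
    low_count = obs_counts < min_proteins
    low_intensity = pd.Series(run_medians < global_med - mad_k * scale, index=ds.runs.index)
    flagged = list(ds.runs.index[low_count | low_intensity])
    if len(flagged) == len(ds.runs):
        raise ValueError("every run flagged as outlier; check the thresholds")
    return flagged


def _groups(ds: LFQDataset) -> dict[str, list[str]]:
    """Condition groups plus the bead-control group, as run-id lists."""
    groups = {
        condition_label(cond): ds.runs_for_condition(cond) for cond in ds.conditions()
    }
    ctrl = list(ds.control_runs)
    if ctrl:
        groups[CONTROL_GROUP] = ctrl
    return groups


def presence_filter(
    ds: LFQDataset, presence_frac: float = 0.6
) -> tuple[LFQDataset, pd.DataFrame]:
    """Step (iv): per group, keep a protein iff observed in >= 60% of the
    group's remaining runs; drop a protein globally only if it survives in
    no group.  Returns the reduced dataset and the proteins x groups
    presence mask."""
    groups = _groups(ds)
    presence = pd.DataFrame(index=ds.proteins.index, columns=list(groups), dtype=bool)
    for gname, runs in groups.items():
        if not runs:
            presence[gname] = False
            continue
        frac = ds.intensity[runs].notna().sum(axis=1) / len(runs)
        presence[gname] = frac >= presence_frac
    keep = presence.any(axis=1)
    out = ds.subset(proteins=ds.proteins.index[keep])
    return out, presence.loc[keep]


def control_enrichment(
    ds: LFQDataset,
    condition: Condition,
    presence: pd.DataFrame | None = None,
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Step (v): moderated-t enrichment of one condition over bead control.

    ``ds`` must be log2-scale and contain the bead-control runs.  Proteins
    are candidates if they pass the presence filter for this condition's
    group (all proteins if ``presence`` is None).  Missing cells are
    classified MNAR/MAR per group and imputed (kNN for MAR, a global
    observed-minimum floor for MNAR by default).  BH adjustment is applied
    across proteins within the condition; the called set is
    ``p_adj < 0.01 and log_fc > 1``.
    """
    params = params or FilterParams()
    if not ds.log2_scale:
        raise ValueError("control_enrichment expects a log2-scale dataset")
    sample_runs = ds.runs_for_condition(condition)
    control_runs = list(ds.control_runs)
    label = condition_label(condition)
    usable_s = [
        r for r in sample_runs if ds.intensity[r].notna().any()
    ]
    usable_c = [r for r in control_runs if ds.intensity[r].notna().any()]
    if len(usable_s) < 2 or len(usable_c) < 2:
        raise ValueError(
            f"condition {label}: fewer than two usable runs on one side"
        )
    candidates = (
        presence.index[presence[label]] if presence is not None else ds.proteins.index
    )
    if len(candidates) == 0:
        return _empty_calls(condition)

    sub = ds.intensity.loc[:, usable_s + usable_c]
    groups = {"sample": usable_s, CONTROL_GROUP: usable_c}
    labels = stats_core.classify_missingness(sub, groups)
    filled = stats_core.impute(
        sub,
        labels,
        groups,
        strategy_mar=params.strategy_mar,
        strategy_mnar=params.strategy_mnar,
        k=params.knn_k,
        seed=params.seed,
    )
    filled = filled.loc[candidates]
    res = stats_core.moderated_t_table(filled[usable_s], filled[usable_c])
    res["p_adj"] = stats_core.adjust_bh(res["p"].to_numpy())
    res["called"] = (res["p_adj"] < params.p_adj_cutoff) & (
        res["log_fc"] > params.logfc_cutoff
    )
    res.insert(0, "condition", label)
    res.index.name = "protein_id"
    return res


def _empty_calls(condition: Condition) -> pd.DataFrame:
    cols = ["condition", "log_fc", "s2_pooled", "t", "df_total", "p", "p_adj", "called"]
    out = pd.DataFrame(columns=cols)
    out.index.name = "protein_id"
    return out


def merge_technical(ds: LFQDataset) -> LFQDataset:
    """Merge technical replicates per biological replicate by the median
    over observed values (all-missing stays missing)."""
    meta = ds.runs
    key_cols = ["genetic_context", "culture_context", "concentration", "bio_rep", "is_control"]
    merged_cols: dict[str, np.ndarray] = {}
    rows = []
    for key, sub in meta.groupby(key_cols, sort=False):
        g, cu, co, b, is_ctrl = key
        run_ids = list(sub.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(ds.intensity[run_ids].to_numpy(dtype=float), axis=1)
        new_id = f"{g}_{cu}_{co}_b{b}"
        merged_cols[new_id] = med
        rows.append(
            dict(
                run_id=new_id,
                genetic_context=g,
                culture_context=cu,
                concentration=co,
                bio_rep=int(b),
                tech_rep=1,
                is_control=bool(is_ctrl),
            )
        )
    runs = pd.DataFrame(rows).set_index("run_id")
    intensity = pd.DataFrame(merged_cols, index=ds.proteins.index)
    return LFQDataset(
        proteins=ds.proteins.copy(),
        runs=runs,
        intensity=intensity,
        log2_scale=ds.log2_scale,
    )


# --------------------------------------------------------------------- #
# pipeline composition
# --------------------------------------------------------------------- #
def run_filter_pipeline(
    ds: LFQDataset, params: FilterParams | None = None
) -> FilterResult:
    """Steps (i)-(v) in canonical order, then technical-replicate merging."""
    params = params or FilterParams()
    report = FilterReport()
    report.record("input", ds)

    ds = remove_flagged(ds)
    report.record("remove_flagged", ds)

    ds = drop_zero_observations(ds)
    report.record("drop_zero_observations", ds)

    outliers = detect_outlier_runs(ds, params.min_proteins, params.mad_k)
    report.removed_runs = outliers
    ds = ds.subset(runs=[r for r in ds.runs.index if r not in set(outliers)])
    report.record("remove_outlier_runs", ds)

    ds, presence = presence_filter(ds, params.presence_frac)
    report.record("presence_filter", ds)
    report.group_sizes = {g: len(r) for g, r in _groups(ds).items()}

    ds_log = ds.to_log2()
    calls: dict[Condition, pd.DataFrame] = {}
    for cond in ds_log.conditions():
        try:
            calls[cond] = control_enrichment(ds_log, cond, presence, params)
        except ValueError as exc:
            report.skipped_conditions.append(f"{condition_label(cond)}: {exc}")
    merged = merge_technical(ds_log)
    report.record("merge_technical", merged)
    return FilterResult(dataset=merged, calls=calls, report=report, presence=presence)


def interactor_sets(result: FilterResult) -> dict:
    """Called interactor ids per condition."""
    return {
        cond: set(tab.index[tab["called"]]) for cond, tab in result.calls.items()
    }


def literature_overlap(identified: Iterable[str], literature: Iterable[str]) -> dict:
    """Overlap report between an identified interactor set and a literature
    interactome: counts, percentage of the literature set recovered, and
    the number of newly reported proteins."""
    ident = set(identified)
    lit = set(literature)
    overlap = ident & lit
    pct = 100.0 * len(overlap) / len(lit) if lit else float("nan")
    return {
        "n_identified": len(ident),
        "n_literature": len(lit),
        "n_overlap": len(overlap),
        "pct_literature_recovered": pct,
        "n_novel": len(ident - lit),
    }
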