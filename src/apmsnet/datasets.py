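"""Core in-memory containers for label-free AP-MS quantification data.

The central carrier is :class:`LFQDataset`: a proteins x runs intensity
matrix on the raw MaxLFQ scale (or log2 of it), together with per-run
experimental metadata and per-protein identification flags.  Missing
observations are stored as NaN, which is distinct from a literal 0 in the
source table; the zero-removal filter is what turns 0 into NaN.

A *condition* is a (genetic context, culture context, concentration)
triple.  The study design crossing four KRAS variants with eleven culture
contexts (unstimulated plus five stimuli at two doses) gives 44 conditions;
with three biological and two technical replicates that is 264 sample runs,
plus bead-only control runs that carry a sentinel context label.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENETIC_CONTEXTS = ("WT", "G12D", "G12V", "G12C")
STIMULI = ("DMOG", "EGF", "IL6", "PGE2", "TNFa")
CULTURE_CONTEXTS = ("unstim",) + STIMULI
CONCENTRATIONS = ("none", "20", "200")  # ng/ml
#: Label used for genetic/culture context on bead-only control runs.
CONTROL_SENTINEL = "control"

#: (genetic_context, culture_context, concentration)
Condition = tuple[str, str, str]

RUN_COLUMNS = (
    "genetic_context",
    "culture_context",
    "concentration",
    "bio_rep",
    "tech_rep",
    "is_control",
)
PROTEIN_COLUMNS = ("gene_name", "flag_site_only", "flag_contaminant", "flag_reverse")


def condition_label(cond: Condition) -> str:
    """Stable string form of a condition, e.g. ``G12D_DMOG_20``."""
    return "_".join(str(c) for c in cond)


def default_culture_grid(
    stimuli: Sequence[str] = STIMULI,
    concentrations: Sequence[str] = ("20", "200"),
) -> list[tuple[str, str]]:
    """The (culture, concentration) pairs of the design: unstimulated plus
    every stimulus at every dose (11 pairs under the defaults)."""
    grid = [("unstim", "none")]
    grid.extend((s, c) for s in stimuli for c in concentrations)
    return grid


@dataclasses.dataclass
class LFQDataset:
    """Proteins x runs LFQ intensity matrix with metadata.

    Attributes
    ----------
    proteins : pd.DataFrame
        Indexed by ``protein_id``; columns ``gene_name``, ``flag_site_only``,
        ``flag_contaminant``, ``flag_reverse``.
    runs : pd.DataFrame
        Indexed by ``run_id``; columns as in :data:`RUN_COLUMNS`.
    intensity : pd.DataFrame
        Rows ``protein_id``, columns ``run_id``.  NaN marks a missing
        observation; values are raw LFQ or log2(LFQ) per ``log2_scale``.
    log2_scale : bool
        Whether ``intensity`` holds log2-transformed values.
    """

    proteins: pd.DataFrame
    runs: pd.DataFrame
    intensity: pd.DataFrame
    log2_scale: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if not self.proteins.index.is_unique:
            dupes = self.proteins.index[self.proteins.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein_id: {dupes}")
        if not self.runs.index.is_unique:
            raise ValueError("duplicate run_id in metadata")
        if list(self.intensity.index) != list(self.proteins.index):
            raise ValueError("intensity rows do not match protein table")
        if list(self.intensity.columns) != list(self.runs.index):
            raise ValueError("intensity columns do not match run table")
        for col in RUN_COLUMNS:
            if col not in self.runs.columns:
                raise ValueError(f"run metadata misses column {col!r}")
        samples = self.runs[~self.runs["is_control"].astype(bool)]
        bad = samples[
            (samples["culture_context"] == "unstim")
            != (samples["concentration"] == "none")
        ]
        if len(bad):
            raise ValueError(
                "culture_context 'unstim' must pair with concentration 'none' "
                f"(offending runs: {bad.index.tolist()})"
            )
        key = samples[
            ["genetic_context", "culture_context", "concentration", "bio_rep", "tech_rep"]
        ]
        if key.duplicated().any():
            raise ValueError("duplicate (condition, bio_rep, tech_rep) in sample runs")
        vals = self.intensity.to_numpy(dtype=float)
        if not self.log2_scale and np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("raw-scale intensities must be non-negative")

    # ------------------------------------------------------------------ #
    @property
    def sample_runs(self) -> pd.Index:
        return self.runs.index[~self.runs["is_control"].astype(bool)]

    @property
    def control_runs(self) -> pd.Index:
        return self.runs.index[self.runs["is_control"].astype(bool)]

    def conditions(self) -> list[Condition]:
        """Unique sample conditions in run-table order."""
        seen: dict[Condition, None] = {}
        sub = self.runs.loc[self.sample_runs]
        for _, row in sub.iterrows():
            cond = (
                str(row["genetic_context"]),
                str(row["culture_context"]),
                str(row["concentration"]),
            )
            seen.setdefault(cond, None)
        return list(seen)

    def runs_for_condition(self, cond: Condition) -> list[str]:
        g, cu, co = cond
        sub = self.runs
        mask = (
            (~sub["is_control"].astype(bool))
            & (sub["genetic_context"].astype(str) == str(g))
            & (sub["culture_context"].astype(str) == str(cu))
            & (sub["concentration"].astype(str) == str(co))
        )
        return list(sub.index[mask])

    # ------------------------------------------------------------------ #
    def subset(
        self,
        proteins: Iterable[str] | None = None,
        runs: Iterable[str] | None = None,
    ) -> "LFQDataset":
        """New dataset restricted to the given protein and/or run ids."""
        pidx = self.proteins.index if proteins is None else pd.Index(list(proteins))
        ridx = self.runs.index if runs is None else pd.Index(list(runs))
        return LFQDataset(
            proteins=self.proteins.loc[pidx].copy(),
            runs=self.runs.loc[ridx].copy(),
            intensity=self.intensity.loc[pidx, ridx].copy(),
            log2_scale=self.log2_scale,
        )

    def copy(self) -> "LFQDataset":
        return LFQDataset(
            proteins=self.proteins.copy(),
            runs=self.runs.copy(),
            intensity=self.intensity.copy(),
            log2_scale=self.log2_scale,
        )

    def to_log2(self) -> "LFQDataset":
        """log2-transform raw intensities (NaN stays NaN, 0 becomes NaN)."""
        if self.log2_scale:
            return self.copy()
        vals = self.intensity.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
        out = self.copy()
        out.intensity = pd.DataFrame(
            logged, index=self.intensity.index, columns=self.intensity.columns
        )
        out.log2_scale = True
        return out

    def from_log2(self) -> "LFQDataset":
        """Back-transform log2 intensities to the raw scale."""
        if not self.log2_scale:
            return self.copy()
        out = self.copy()
        out.log2_scale = False
        out.intensity = np.power(2.0, self.intensity)
        return out


def make_run_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a run-metadata frame from dicts carrying ``run_id`` plus
    the :data:`RUN_COLUMNS` fields."""
    df = pd.DataFrame(rows).set_index("run_id")
    df["bio_rep"] = df["bio_rep"].astype(int)
    df["tech_rep"] = df["tech_rep"].astype(int)
    df["is_control"] = df["is_control"].astype(bool)
    return df[list(RUN_COLUMNS)]
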