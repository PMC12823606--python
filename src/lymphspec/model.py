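"""Statistical model for imaging-based lymphedema staging.

:class:`HsiStagingModel` is built from per-measurement interlimb LWR
differences (dLWR) and, optionally, the clinically diagnosed stage of
each measurement. ``fit()`` performs the k = 3 hierarchical clustering
that defines the imaging stage (low / mid / high), and — when clinical
stages are supplied — the accompanying inference: Spearman correlation
between clinical and imaging stage, two-sided Mann-Whitney U tests
between adjacent clinical stages, and per-stage normality diagnostics.
Results live on :class:`HsiStagingResults`, which renders a
statsmodels-style ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as lstats

__all__ = ["HsiStagingModel", "HsiStagingResults"]


class HsiStagingModel:
    """Staging of measurements by clustering their dLWR values.

    Parameters
    ----------
    delta_lwr:
        Signed affected-minus-unaffected LWR per measurement. Water
        accumulation depresses the water-band reflectance of the
        affected side, so larger (more positive) dLWR means a stronger
        lymphedema signature.
    le_stage:
        Optional clinical stage (0-III) per measurement; enables the
        inference layer.
    k, linkage:
        Number of imaging stages and agglomerative linkage (Ward by
        default).
    direction:
        +1 stages on signed dLWR (default; high imaging stage = large
        positive dLWR), -1 stages on its negative.
    """

    def __init__(self, delta_lwr, le_stage=None, k: int = 3,
                 linkage: str = "ward", direction: int = 1):
        self.delta_lwr = np.asarray(delta_lwr, dtype=float)
        self.le_stage = None if le_stage is None else np.asarray(le_stage)
        if self.le_stage is not None and self.le_stage.size != self.delta_lwr.size:
            raise ValueError("le_stage length must match delta_lwr")
        if direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        self.k = k
        self.linkage = linkage
        self.direction = direction

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, value_col: str = "d_lwr",
                       stage_col: str | None = "isl_stage", **kwargs
                       ) -> "HsiStagingModel":
        stage = None
        if stage_col is not None and stage_col in data.columns:
            stage = data[stage_col].to_numpy()
        return cls(data[value_col].to_numpy(), le_stage=stage, **kwargs)

    def fit(self) -> "HsiStagingResults":
        staging = lstats.hsi_stage(self.direction * self.delta_lwr,
                                   k=self.k, linkage=self.linkage)
        return HsiStagingResults(self, staging)


class HsiStagingResults:
    """Fitted imaging staging plus the associated inference."""

    def __init__(self, model: HsiStagingModel, staging: lstats.HsiStaging):
        self.model = model
        self.staging = staging
        self.labels_ = list(staging.labels)
        self.stage_codes_ = staging.label_codes()
        self.cluster_means_ = model.direction * staging.cluster_means
        self.nobs = staging.values.size

        self.spearman_r_: float | None = None
        self.adjacent_tests_: dict[str, lstats.TestResult] = {}
        self.normality_: dict[int, lstats.TestResult] = {}
        if model.le_stage is not None:
            stages = np.asarray(model.le_stage, dtype=float)
            self.spearman_r_ = lstats.spearman(stages, self.stage_codes_)
            uniq = np.unique(stages).astype(int)
            for s in uniq:
                grp = model.delta_lwr[stages == s]
                try:
                    self.normality_[int(s)] = lstats.normality_omnibus(grp)
                except ValueError:  # too few / constant: shape not assessable
                    pass
            for a, b in zip(uniq[:-1], uniq[1:]):
                ga = model.delta_lwr[stages == a]
                gb = model.delta_lwr[stages == b]
                self.adjacent_tests_[f"stage {a} vs {b}"] = lstats.mann_whitney_u(ga, gb)

    def staging_table(self) -> pd.DataFrame:
        """One row per measurement: dLWR, imaging stage label and code."""
        out = pd.DataFrame({
            "d_lwr": self.model.delta_lwr,
            "hsi_stage": self.labels_,
            "hsi_stage_code": self.stage_codes_,
        })
        if self.model.le_stage is not None:
            out["isl_stage"] = self.model.le_stage
        return out

    def summary(self) -> str:
        lines = [
            "HSI staging results",
            "=" * 58,
            f"measurements:        {self.nobs}",
            f"clusters (k):        {self.staging.k}  [{self.model.linkage} linkage]",
        ]
        counts = pd.Series(self.labels_).value_counts()
        for lab, mean in zip(lstats._stage_names(self.staging.k), self.cluster_means_):
            lines.append(f"  {lab:<5} n={int(counts.get(lab, 0)):<4} "
                         f"mean dLWR = {mean:+.4f}")
        if self.spearman_r_ is not None:
            lines.append("-" * 58)
            lines.append(f"Spearman r (clinical stage, imaging stage): "
                         f"{self.spearman_r_:.3f}")
            for name, res in self.adjacent_tests_.items():
                lines.append(f"  Mann-Whitney {name}: U={res.statistic:.1f} "
                             f"p={res.p_value:.3g} n={res.n} [{res.method}]")
            for s, res in self.normality_.items():
                flag = " (!)" if res.note else ""
                lines.append(f"  normality stage {s}: p={res.p_value:.3g} "
                             f"n={res.n[0]}{flag}")
        lines.append("=" * 58)
        return "\n".join(lines)
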