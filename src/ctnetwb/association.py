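"""Covariate-adjusted association between network topology and well-being.

For every (parcel, node metric, well-being dimension) triple an ordinary
least squares fit of

    wellbeing = a1*age + a2*sex + a3*education + a4*ICV + a5*meanCT
                + beta*metric + gamma

tests the metric term. The reported effect size is the *partial* correlation
of metric and outcome given the covariates, recovered from the t statistic:
r_p = sign(t) * sqrt(t^2 / (t^2 + df)); a zero-order correlation is also
available. Benjamini-Hochberg FDR runs within each (metric x dimension)
family of 32 parcel tests, per the study design; pooling across metrics is
available behind a flag for sensitivity analysis. Global efficiency, a
single graph-level value per subject, is tested per dimension without the
parcel loop and without FDR.

The module is organised statsmodels-style: build a
:class:`WellbeingTopologyModel` from the metrics / scores / covariate
tables (or directly from a synthetic cohort), call :meth:`fit`, and read
estimates, q-values and diagnostics off the returned
:class:`WellbeingTopologyResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import DIMENSIONS

__all__ = [
    "GlmFit",
    "fit_glm",
    "fdr_bh",
    "run_association",
    "WellbeingTopologyModel",
    "WellbeingTopologyResults",
]

COVARIATE_COLUMNS = ["age", "sex", "education_years", "icv_mm3", "mean_ct_mm"]


@dataclass(frozen=True)
class GlmFit:
    """One OLS fit of a well-being score on covariates plus a metric term."""

    alpha: np.ndarray = field(repr=False)  # 5 covariate coefficients
    beta: float  # metric coefficient
    gamma: float  # intercept
    beta_se: float
    t_stat: float
    p_value: float
    partial_r: float
    df_resid: int


def _design(covariates: pd.DataFrame) -> np.ndarray:
    cov = covariates.copy()
    if cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "M").astype(float)
    X = cov[COVARIATE_COLUMNS].to_numpy(dtype=float)
    if np.any(X[:, 3] <= 0) or np.any(X[:, 4] <= 0):
        raise ValueError("ICV and mean CT must be positive")
    if np.any(~np.isfinite(X)):
        raise ValueError("covariates contain missing values")
    return X


def fit_glm(outcome, metric, covariates: pd.DataFrame) -> GlmFit:
    """OLS of outcome on the five covariates, the metric term and intercept."""
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(metric, dtype=float)
    Z = _design(covariates)
    n = y.size
    if not (len(m) == len(Z) == n):
        raise ValueError("outcome, metric and covariates must be aligned")
    if n <= 7:
        raise ValueError("need more than 7 subjects for 7 parameters")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; GLM undefined")
    X = np.column_stack([Z, m, np.ones(n)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        labels = COVARIATE_COLUMNS + ["metric"]
        const = [labels[k] for k in range(6) if np.ptp(X[:, k]) == 0]
        detail = f" (constant columns: {const})" if const else ""
        raise ValueError(f"design matrix is rank deficient{detail}")
    beta_hat, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov_beta = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov_beta[5, 5]))
    t = float(beta_hat[5] / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    partial_r = float(np.sign(t) * np.sqrt(t * t / (t * t + df)))
    return GlmFit(
        alpha=beta_hat[:5],
        beta=float(beta_hat[5]),
        gamma=float(beta_hat[6]),
        beta_se=se,
        t_stat=t,
        p_value=p,
        partial_r=partial_r,
        df_resid=df,
    )


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (monotone q-values, significance flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def _residualizer(Z: np.ndarray):
    Q, _ = np.linalg.qr(np.column_stack([Z, np.ones(len(Z))]))

    def resid(x: np.ndarray) -> np.ndarray:
        return x - Q @ (Q.T @ x)

    return resid


class WellbeingTopologyModel:
    """GLM association model between parcel topology and well-being scores.

    Parameters
    ----------
    node_metrics : long-format table (subject_id, parcel, metric, value)
    scores : table (subject_id, emotional, psychological, social, total)
    covariates : table (subject_id, age, sex, education_years, icv_mm3,
        mean_ct_mm)
    eglob : optional per-subject global efficiency (subject_id, value)
    """

    def __init__(
        self,
        node_metrics: pd.DataFrame,
        scores: pd.DataFrame,
        covariates: pd.DataFrame,
        eglob: pd.DataFrame | None = None,
    ) -> None:
        ids = list(scores["subject_id"].astype(str))
        if set(covariates["subject_id"].astype(str)) != set(ids):
            raise ValueError("scores and covariates cover different subjects")
        if set(node_metrics["subject_id"].astype(str)) != set(ids):
            raise ValueError("metrics and scores cover different subjects")
        self.subject_ids = ids
        self.scores = scores.set_index(scores["subject_id"].astype(str)).loc[ids]
        cov = covariates.copy()
        self.covariates = cov.set_index(cov["subject_id"].astype(str)).loc[ids]
        self.node_metrics = node_metrics
        self.parcels = list(dict.fromkeys(node_metrics["parcel"]))
        self.metrics = list(dict.fromkeys(node_metrics["metric"]))
        self.eglob = None
        if eglob is not None:
            self.eglob = eglob.set_index(eglob["subject_id"].astype(str)).loc[ids]
        # wide (subject x parcel) value matrix per metric, in subject order
        self._wide = {
            metric: sub.pivot(index="subject_id", columns="parcel", values="value")
            .loc[ids, self.parcels]
            .to_numpy(dtype=float)
            for metric, sub in node_metrics.groupby("metric")
        }

    @classmethod
    def from_cohort(
        cls,
        cohort,
        n_bins: int = 30,
        distance_transform: str = "reciprocal",
        subscale_map: dict | None = None,
    ) -> "WellbeingTopologyModel":
        """Run the full network chain on a cohort and assemble the model."""
        from .behavior import score_table
        from .pipeline import compute_network_metrics
        from .thickness import mean_cortical_thickness

        metrics, eglob = compute_network_metrics(
            cohort.thickness,
            cohort.parcel_table,
            n_bins=n_bins,
            distance_transform=distance_transform,
        )
        scores = score_table(cohort.behavior, subscale_map=subscale_map)
        cov = cohort.covariates.copy()
        cov["mean_ct_mm"] = [
            mean_cortical_thickness(s) for s in cohort.thickness
        ]
        return cls(metrics, scores, cov, eglob=eglob)

    def fit(
        self,
        q: float = 0.05,
        pool_metrics: bool = False,
        zero_order: bool = False,
    ) -> "WellbeingTopologyResults":
        """Fit every (parcel, metric, dimension) GLM and apply BH FDR.

        Uses the Frisch-Waugh-Lovell decomposition (exactly equivalent to the
        full OLS fit) to vectorise the per-parcel fits within one family.
        """
        Z = _design(self.covariates)
        resid = _residualizer(Z)
        n = len(self.subject_ids)
        df = n - 7
        rows = []
        for metric in self.metrics:
            M = self._wide[metric]
            E = resid(M)
            E_ss = (E * E).sum(axis=0)
            for dim in DIMENSIONS:
                y = self.scores[dim].to_numpy(dtype=float)
                ey = resid(y)
                ey_ss = float(ey @ ey)
                if ey_ss <= 0:
                    raise ValueError(
                        f"outcome {dim!r} has no residual variance given covariates"
                    )
                # a metric with no residual variance (constant, or collinear
                # with the covariates) carries no evidence: r = 0, p = 1
                degenerate = E_ss <= 1e-12 * np.abs(M).sum(axis=0) ** 2 / len(M)
                safe_ss = np.where(degenerate, 1.0, E_ss)
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.where(degenerate, 0.0, (ey @ E) / np.sqrt(ey_ss * safe_ss))
                    beta = np.where(degenerate, 0.0, (ey @ E) / safe_ss)
                    t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
                p = 2.0 * stats.t.sf(np.abs(t), df)
                zr = None
                if zero_order:
                    yc = y - y.mean()
                    Mc = M - M.mean(axis=0)
                    zr = (yc @ Mc) / np.sqrt((yc @ yc) * (Mc * Mc).sum(axis=0))
                for k, parcel in enumerate(self.parcels):
                    row = {
                        "parcel": parcel,
                        "metric": metric,
                        "dimension": dim,
                        "beta": beta[k],
                        "t": t[k],
                        "p": p[k],
                        "partial_r": r[k],
                        "df_resid": df,
                    }
                    if zero_order:
                        row["zero_order_r"] = zr[k]
                    rows.append(row)
        table = pd.DataFrame(rows)

        # BH within each family (default: the 32 parcels of one metric x dimension)
        family_cols = ["dimension"] if pool_metrics else ["metric", "dimension"]
        qvals = np.empty(len(table))
        flags = np.empty(len(table), dtype=bool)
        for _, idx in table.groupby(family_cols).groups.items():
            qv, fl = fdr_bh(table.loc[idx, "p"].to_numpy(), q=q)
            qvals[table.index.get_indexer(idx)] = qv
            flags[table.index.get_indexer(idx)] = fl
        table["q"] = qvals
        table["significant"] = flags

        eglob_table = None
        if self.eglob is not None:
            eg = self.eglob["value"].to_numpy(dtype=float)
            erows = []
            for dim in DIMENSIONS:
                f = fit_glm(self.scores[dim].to_numpy(dtype=float), eg, self.covariates)
                erows.append(
                    {
                        "metric": "Eglob",
                        "dimension": dim,
                        "beta": f.beta,
                        "t": f.t_stat,
                        "p": f.p_value,
                        "partial_r": f.partial_r,
                        "df_resid": f.df_resid,
                    }
                )
            eglob_table = pd.DataFrame(erows)

        return WellbeingTopologyResults(
            model=self, table=table, eglob_table=eglob_table, q=q
        )


@dataclass
class WellbeingTopologyResults:
    """Estimates, FDR-corrected significance and summaries of the fits."""

    model: WellbeingTopologyModel
    table: pd.DataFrame
    eglob_table: pd.DataFrame | None
    q: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)

    def family(self, metric: str, dimension: str) -> pd.DataFrame:
        sel = (self.table["metric"] == metric) & (self.table["dimension"] == dimension)
        return self.table[sel].reset_index(drop=True)

    def top_hit(self, metric: str, dimension: str) -> pd.Series:
        fam = self.family(metric, dimension)
        return fam.loc[fam["p"].idxmin()]

    def dimension_effect_sizes(self) -> pd.DataFrame:
        """Per-dimension partial r at every total-score-significant hit.

        For each (parcel, metric) significant for the total score, report the
        partial correlation of the three component dimensions at the same
        parcel and metric.
        """
        hits = self.table[
            (self.table["dimension"] == "total") & self.table["significant"]
        ]
        rows = []
        for _, hit in hits.iterrows():
            sel = self.table[
                (self.table["parcel"] == hit["parcel"])
                & (self.table["metric"] == hit["metric"])
            ]
            row = {"parcel": hit["parcel"], "metric": hit["metric"],
                   "total_partial_r": hit["partial_r"]}
            for dim in ("emotional", "psychological", "social"):
                row[f"{dim}_partial_r"] = float(
                    sel.loc[sel["dimension"] == dim, "partial_r"].iloc[0]
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n = len(self.model.subject_ids)
        lines = [
            "Well-being ~ topology GLM association results",
            "=" * 46,
            f"subjects: {n}   parcels: {len(self.model.parcels)}   "
            f"metrics: {len(self.model.metrics)}   FDR q < {self.q}",
            f"fits: {len(self.table)} "
            f"({len(self.model.metrics)} metrics x 4 dimensions x "
            f"{len(self.model.parcels)} parcels)",
            "",
        ]
        sig = self.significant
        if len(sig) == 0:
            lines.append("No FDR-significant associations.")
        else:
            lines.append(f"{len(sig)} FDR-significant association(s):")
            for _, r in sig.iterrows():
                lines.append(
                    f"  {r['metric']:>7s} in {r['parcel']:<26s} ~ "
                    f"{r['dimension']:<13s} partial r = {r['partial_r']:+.4f}, "
                    f"q = {r['q']:.4f}"
                )
        if self.eglob_table is not None:
            lines.append("")
            lines.append("Global efficiency (graph-level, uncorrected):")
            for _, r in self.eglob_table.iterrows():
                lines.append(
                    f"  Eglob ~ {r['dimension']:<13s} partial r = "
                    f"{r['partial_r']:+.4f}, p = {r['p']:.4f}"
                )
        return "\n".join(lines)

    def plot(self, metric: str, dimension: str, ax=None):
        """Manhattan-style plot of -log10 p per parcel for one family."""
        import matplotlib.pyplot as plt

        fam = self.family(metric, dimension)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3.5))
        colors = np.where(fam["significant"], "C3", "C0")
        ax.bar(np.arange(len(fam)), -np.log10(fam["p"]), color=colors)
        ax.set_xticks(np.arange(len(fam)))
        ax.set_xticklabels(fam["parcel"], rotation=90, fontsize=6)
        ax.set_ylabel("-log10 p")
        ax.set_title(f"{metric} ~ {dimension} (FDR q < {self.q})")
        return ax


def run_association(
    node_metrics: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    eglob: pd.DataFrame | None = None,
    q: float = 0.05,
    pool_metrics: bool = False,
    zero_order: bool = False,
) -> WellbeingTopologyResults:
    """Functional wrapper: build the model and fit it in one call."""
    model = WellbeingTopologyModel(node_metrics, scores, covariates, eglob=eglob)
    return model.fit(q=q, pool_metrics=pool_metrics, zero_order=zero_order)
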