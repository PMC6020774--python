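"""Brain-behavior correlation battery.

Pearson and one-covariate partial correlations with one-tailed tests
(positive-association alternative), Steiger's Z1* test for comparing two
dependent correlations sharing one variable, Benjamini-Hochberg FDR over a
configured family of brain-behavior tests, and assembly of a typed report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "SteigerComparison",
    "BatteryReport",
    "CorrTest",
    "SteigerTest",
    "BatterySpec",
    "pearson_one_tailed",
    "partial_corr_one_tailed",
    "steiger_z",
    "bh_fdr",
    "run_battery",
    "default_battery",
]


@dataclass
class CorrelationResult:
    label: str
    r: float
    n: int
    df: int
    t_or_z: float
    p_raw: float
    tail: str = "one"
    covariates: tuple[str, ...] = ()
    p_fdr: Optional[float] = None


@dataclass(frozen=True)
class SteigerComparison:
    label: str
    r12: float
    r13: float
    r23: float
    n: int
    z: float
    p_two_tailed: float


def _corr_p(r: float, df: int, tail: str) -> tuple[float, float]:
    """t statistic and p-value for a correlation with the given df."""
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = 0.0 if (tail == "two" or r > 0) else 1.0
        return t, p
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    if tail == "one":
        p = float(sps.t.sf(t, df))  # H1: positive association
    elif tail == "two":
        p = float(2 * sps.t.sf(abs(t), df))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(t), p


def pearson_one_tailed(
    x: Sequence[float], y: Sequence[float], tail: str = "one", label: str = ""
) -> CorrelationResult:
    """Pearson correlation with a one-tailed (positive) test by default.

    t = r * sqrt(n-2) / sqrt(1-r^2), df = n - 2; the one-tailed p is the
    upper-tail probability (a-priori positive-association hypothesis).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length x, y with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2
    t, p = _corr_p(r, df, tail)
    return CorrelationResult(label=label, r=r, n=x.size, df=df, t_or_z=t, p_raw=p, tail=tail)


def partial_corr_one_tailed(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    tail: str = "one",
    label: str = "",
    covariate_name: str = "z",
) -> CorrelationResult:
    """Partial correlation of x and y controlling for one covariate z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)), tested with
    df = n - 3.  Equivalent to correlating the two OLS residual vectors.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if not (x.size == y.size == z.size) or x.size < 4:
        raise ValueError("need equal-length x, y, z with n >= 4")
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    if min(1 - rxz**2, 1 - ryz**2) < 1e-12:  # collinear up to floating error
        raise ValueError("degenerate covariate: |r_xz| or |r_yz| is 1")
    denom = (1 - rxz**2) * (1 - ryz**2)
    r = float((rxy - rxz * ryz) / np.sqrt(denom))
    df = x.size - 3
    t, p = _corr_p(r, df, tail)
    return CorrelationResult(
        label=label, r=r, n=x.size, df=df, t_or_z=t, p_raw=p, tail=tail,
        covariates=(covariate_name,),
    )


def _check_psd_triple(r12: float, r13: float, r23: float) -> None:
    c = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")


def steiger_z(r12: float, r13: float, r23: float, n: int, label: str = "") -> SteigerComparison:
    """Steiger's Z1* for two dependent correlations sharing variable 1.

    Fisher-transforms r12 and r13 and uses the Dunn-Clark covariance
    evaluated at the pooled correlation rbar = (r12 + r13)/2:

        psi  = r23 (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r23^2) / 2
        sbar = psi / (1 - rbar^2)^2
        Z    = (z12 - z13) sqrt((n - 3) / (2 - 2 sbar))

    Two-tailed normal p-value.
    """
    for r in (r12, r13, r23):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    _check_psd_triple(r12, r13, r23)
    z12 = np.arctanh(r12)
    z13 = np.arctanh(r13)
    rbar = (r12 + r13) / 2.0
    psi = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
    sbar = psi / (1 - rbar**2) ** 2
    z = float((z12 - z13) * np.sqrt((n - 3) / (2 - 2 * sbar)))
    p = float(2 * sps.norm.sf(abs(z)))
    return SteigerComparison(label=label, r12=r12, r13=r13, r23=r23, n=n, z=z, p_two_tailed=p)


def williams_t(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Williams' t variant of the dependent-correlation comparison."""
    _check_psd_triple(r12, r13, r23)
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    rbar = (r12 + r13) / 2.0
    t = (r12 - r13) * np.sqrt(
        (n - 1) * (1 + r23)
        / (2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3)
    )
    p = float(2 * sps.t.sf(abs(t), n - 3))
    return float(t), p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in original order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Battery


@dataclass(frozen=True)
class CorrTest:
    x: str  # brain measure column
    y: str  # behavior column
    covariate: Optional[str] = None
    tail: str = "one"

    @property
    def label(self) -> str:
        cov = f"|{self.covariate}" if self.covariate else ""
        return f"{self.x}~{self.y}{cov}"


@dataclass(frozen=True)
class SteigerTest:
    """Compare corr(shared, a) against corr(shared, b)."""

    shared: str
    a: str
    b: str

    @property
    def label(self) -> str:
        return f"{self.shared}:{self.a}-vs-{self.b}"


@dataclass
class BatterySpec:
    correlations: list[CorrTest]
    steiger: list[SteigerTest] = field(default_factory=list)
    q: float = 0.05
    family: str = "all brain-behavior correlations"


@dataclass
class BatteryReport:
    correlations: list[CorrelationResult]
    steiger: list[SteigerComparison]
    q: float
    family: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": c.label, "kind": "correlation", "r": c.r, "n": c.n,
                "df": c.df, "stat": c.t_or_z, "p_raw": c.p_raw,
                "p_fdr": c.p_fdr, "tail": c.tail,
                "covariates": ",".join(c.covariates),
            }
            for c in self.correlations
        ] + [
            {
                "label": s.label, "kind": "steiger", "r": s.r12 - s.r13, "n": s.n,
                "df": np.nan, "stat": s.z, "p_raw": s.p_two_tailed,
                "p_fdr": np.nan, "tail": "two", "covariates": "",
            }
            for s in self.steiger
        ]
        return pd.DataFrame(rows)

    def significant(self) -> list[CorrelationResult]:
        return [c for c in self.correlations if c.p_fdr is not None and c.p_fdr < self.q]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "q": self.q,
                    "family": self.family,
                    "entries": self.to_frame().replace({np.nan: None}).to_dict("records"),
                },
                fh,
                indent=2,
            )


def scatter_plot(x, y, path, covariate=None, xlabel: str = "x", ylabel: str = "y") -> None:
    """Scatter plot of a brain-behavior pair; with a covariate, both axes
    show standardized residuals after regressing the covariate out."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array(x, float)
    y = np.array(y, float)
    if covariate is not None:
        z = np.asarray(covariate, float)
        Z = np.column_stack([np.ones_like(z), z])
        for arr in (x, y):
            beta, *_ = np.linalg.lstsq(Z, arr, rcond=None)
            arr -= Z @ beta
        x = x / x.std(ddof=1)
        y = y / y.std(ddof=1)
        xlabel += " (std. residual)"
        ylabel += " (std. residual)"
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=25, edgecolor="k", linewidth=0.5)
    b, a = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 2)
    ax.plot(xs, a + b * xs, color="firebrick")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    r = np.corrcoef(x, y)[0, 1]
    ax.set_title(f"r = {r:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_battery(cohort: pd.DataFrame, spec: BatterySpec) -> BatteryReport:
    """Run the configured correlation battery on a cohort table.

    Correlation tests are one-tailed by default and FDR-corrected together
    (one family per battery run); Steiger comparisons are two-tailed and
    reported uncorrected.
    """
    needed = {t.x for t in spec.correlations} | {t.y for t in spec.correlations}
    needed |= {t.covariate for t in spec.correlations if t.covariate}
    needed |= {t.shared for t in spec.steiger} | {t.a for t in spec.steiger} | {t.b for t in spec.steiger}
    missing = needed - set(cohort.columns)
    if missing:
        raise KeyError(f"cohort table missing columns: {sorted(missing)}")

    results: list[CorrelationResult] = []
    for t in spec.correlations:
        if t.covariate:
            res = partial_corr_one_tailed(
                cohort[t.x], cohort[t.y], cohort[t.covariate],
                tail=t.tail, label=t.label, covariate_name=t.covariate,
            )
        else:
            res = pearson_one_tailed(cohort[t.x], cohort[t.y], tail=t.tail, label=t.label)
        results.append(res)
    if results:
        adj = bh_fdr([c.p_raw for c in results])
        for c, a in zip(results, adj):
            c.p_fdr = float(a)

    comparisons: list[SteigerComparison] = []
    n = len(cohort)
    for t in spec.steiger:
        r12 = float(np.corrcoef(cohort[t.shared], cohort[t.a])[0, 1])
        r13 = float(np.corrcoef(cohort[t.shared], cohort[t.b])[0, 1])
        r23 = float(np.corrcoef(cohort[t.a], cohort[t.b])[0, 1])
        comparisons.append(steiger_z(r12, r13, r23, n, label=t.label))

    return BatteryReport(results, comparisons, q=spec.q, family=spec.family)


def default_battery(
    fa_columns: Sequence[str] = ("uf_fa", "ifof_fa", "control_fa"),
    strength_column: str = "tract_strength",
    size_column: str = "target_size",
    behaviors: Sequence[str] = ("mean_high_recall", "mean_low_recall", "mean_selectivity"),
    q: float = 0.05,
) -> BatterySpec:
    """The study-style battery: per-tract FA vs each behavior (Pearson,
    one-tailed), seed-target tract strength vs each behavior (partial,
    controlling target-ROI size), plus high-vs-low Steiger comparisons."""
    corr = [CorrTest(fa, beh) for fa in fa_columns for beh in behaviors]
    corr += [CorrTest(strength_column, beh, covariate=size_column) for beh in behaviors]
    steiger = [SteigerTest(col, behaviors[0], behaviors[1]) for col in (*fa_columns, strength_column)]
    return BatterySpec(correlations=corr, steiger=steiger, q=q)
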