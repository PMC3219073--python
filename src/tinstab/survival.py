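"""TIN-stratified survival analysis.

Patients are grouped by transcriptome-instability status (sTIN, oTIN,
either, or both) and compared by Kaplan-Meier estimation, the log-rank
(Mantel-Cox) test, and Cox proportional-hazards regression.  The Cox
model maximizes the partial likelihood by Newton's method with Efron's
tie correction (Breslow available); hazard ratios carry Wald 95%
confidence intervals exp(beta +/- 1.96 SE).

Categorical covariates are dummy-coded against declared reference levels:
stage II, microsatellite-stable, female, right colon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .io import ValidationError

logger = logging.getLogger("tinstab")

__all__ = [
    "build_survival_groups", "kaplan_meier", "KaplanMeierResult",
    "logrank_test", "cox_ph", "CoxModel", "CoxResults", "build_design",
]

SCHEMES = ("sTIN", "oTIN", "either", "both")
REFERENCE_LEVELS = {"stage": "II", "sex": "F", "location": "right"}


def build_survival_groups(profiles: pd.DataFrame, clinical: pd.DataFrame,
                          scheme: str = "sTIN",
                          allow_subset: bool = False) -> pd.DataFrame:
    """Join TIN profiles with clinical data and define the comparison group.

    The returned table has one row per patient with the clinical columns
    plus a boolean ``group`` (TIN-positive under the chosen scheme).
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    missing = profiles.index.difference(clinical.index)
    if len(missing):
        if not allow_subset:
            raise ValidationError(
                f"clinical record(s) missing for {len(missing)} profiled sample(s), "
                f"e.g. {list(missing)[:5]}"
            )
        logger.warning("dropping %d samples without clinical records", len(missing))
    common = profiles.index.intersection(clinical.index)
    if len(common) == 0:
        raise ValidationError("profiles and clinical data share no samples")
    prof = profiles.loc[common]
    table = clinical.loc[common].copy()
    if scheme == "sTIN":
        group = prof["is_sTIN"]
    elif scheme == "oTIN":
        group = prof["is_oTIN"]
    elif scheme == "either":
        group = prof["is_sTIN"] | prof["is_oTIN"]
    else:
        group = prof["is_sTIN"] & prof["is_oTIN"]
    table["group"] = group.astype(bool)
    n_pos = int(table["group"].sum())
    logger.info("survival groups (%s): %d positive vs %d rest",
                scheme, n_pos, len(table) - n_pos)
    if n_pos == 0 or n_pos == len(table):
        raise ValidationError(
            f"scheme {scheme!r} yields a degenerate split "
            f"({n_pos} of {len(table)} positive)"
        )
    return table


@dataclass
class KaplanMeierResult:
    """Product-limit survival curves per group."""

    fitters: dict               # group label -> fitted KaplanMeierFitter

    def survival_at(self, t: float) -> dict:
        """Right-continuous survival probability at time t per group."""
        return {g: float(kmf.predict(t)) for g, kmf in self.fitters.items()}

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g, kmf in self.fitters.items():
            kmf.plot_survival_function(ax=ax, label=str(g))
        ax.set_xlabel("years")
        ax.set_ylabel("disease-specific survival")
        return ax


def kaplan_meier(table: pd.DataFrame, group_col: str = "group") -> KaplanMeierResult:
    """Kaplan-Meier estimator per group (events precede censorings at ties)."""
    fitters = {}
    for g, sub in table.groupby(group_col):
        if len(sub) == 0:
            raise ValidationError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_years"], sub["event"], label=str(g))
        fitters[g] = kmf
    if not fitters:
        raise ValidationError("no groups to fit")
    return KaplanMeierResult(fitters=fitters)


def logrank_test(table: pd.DataFrame, group_col: str = "group"
                 ) -> tuple[float, float]:
    """Mantel-Cox log-rank test between two groups; returns (chi2, p)."""
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValidationError(f"log-rank test needs exactly 2 groups, got {len(groups)}")
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("one group is empty")
    if table["event"].sum() == 0:
        raise ValidationError("no events in either group")
    res = _lifelines_logrank(a["time_years"], b["time_years"],
                             a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


def build_design(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Dummy-code the requested covariates against the reference levels."""
    cols = {}
    for cov in covariates:
        if cov == "group":
            cols["group"] = table["group"].astype(float)
        elif cov in REFERENCE_LEVELS:
            ref = REFERENCE_LEVELS[cov]
            for level in sorted(table[cov].astype(str).unique()):
                if level != ref:
                    cols[f"{cov}_{level}"] = (table[cov].astype(str) == level
                                              ).astype(float)
        elif cov in table.columns:
            cols[cov] = table[cov].astype(float)
        else:
            raise ValidationError(f"unknown covariate {cov!r}")
    X = pd.DataFrame(cols, index=table.index)
    for c in X.columns:
        if X[c].nunique() <= 1:
            raise ValidationError(f"covariate {c!r} is constant")
    return X


def _efron_breslow_quantities(beta, X, time, event, ties):
    """Log partial likelihood, gradient and information at ``beta``."""
    n, p = X.shape
    order = np.lexsort((1 - event, time))  # time asc; events before censorings
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    w = np.exp(eta)
    # suffix sums over the risk set {i : t_i >= t}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    XX = Xs[:, :, None] * Xs[:, None, :]
    S2 = np.cumsum((w[:, None, None] * XX)[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        deaths = [k for k in range(i, j) if es[k] == 1]
        d = len(deaths)
        if d:
            xd = Xs[deaths]
            wd = w[deaths]
            sum_eta = eta[deaths].sum()
            s0, s1, s2 = S0[i], S1[i], S2[i]
            if ties == "breslow" or d == 1:
                loglik += sum_eta - d * np.log(s0)
                grad += xd.sum(axis=0) - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
            else:  # efron
                s0d = wd.sum()
                s1d = (wd[:, None] * xd).sum(axis=0)
                s2d = (wd[:, None, None] * xd[:, :, None] * xd[:, None, :]).sum(axis=0)
                loglik += sum_eta
                grad += xd.sum(axis=0)
                for l in range(d):
                    f = l / d
                    den = s0 - f * s0d
                    num1 = s1 - f * s1d
                    num2 = s2 - f * s2d
                    loglik -= np.log(den)
                    grad -= num1 / den
                    info += num2 / den - np.outer(num1, num1) / den**2
        i = j
    return loglik, grad, info


class CoxModel:
    """Cox proportional-hazards regression on a survival table.

    ``covariates`` name columns of the table ("group" plus any of stage,
    msi, age, sex, location); categorical covariates are dummy-coded
    against the module's reference levels.
    """

    def __init__(self, table: pd.DataFrame, covariates: list[str],
                 ties: str = "efron"):
        if ties not in ("efron", "breslow"):
            raise ValidationError(f"unknown tie method {ties!r}")
        event_times = table.loc[table["event"] == 1, "time_years"]
        if event_times.nunique() < 2:
            raise ValidationError("need at least 2 distinct event times")
        self.table = table
        self.design = build_design(table, covariates)
        self.ties = ties

    def fit(self, tol: float = 1e-8, max_iter: int = 50) -> "CoxResults":
        X = self.design.to_numpy(dtype=float)
        names = list(self.design.columns)
        # center for numerical stability; shifts cancel in the partial likelihood
        X = X - X.mean(axis=0)
        time = self.table["time_years"].to_numpy(dtype=float)
        event = self.table["event"].to_numpy(dtype=int)
        p = X.shape[1]
        beta = np.zeros(p)
        loglik, grad, info = _efron_breslow_quantities(beta, X, time, event, self.ties)
        for it in range(max_iter):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                if np.abs(beta).max() > 5:
                    worst = names[int(np.argmax(np.abs(beta)))]
                    raise ValidationError(
                        f"monotone partial likelihood (perfect separation) for "
                        f"covariate {worst!r}"
                    ) from None
                raise ValidationError(
                    "singular information matrix: collinear covariates among "
                    + ", ".join(names)
                ) from None
            new_beta = beta + step
            new_ll, new_grad, new_info = _efron_breslow_quantities(
                new_beta, X, time, event, self.ties)
            # step-halving keeps the likelihood climbing
            halvings = 0
            while new_ll < loglik - 1e-12 and halvings < 20:
                step /= 2
                new_beta = beta + step
                new_ll, new_grad, new_info = _efron_breslow_quantities(
                    new_beta, X, time, event, self.ties)
                halvings += 1
            beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
            if np.abs(beta).max() > 50:
                worst = names[int(np.argmax(np.abs(beta)))]
                raise ValidationError(
                    f"monotone partial likelihood (perfect separation) for "
                    f"covariate {worst!r}"
                )
            if np.abs(step).max() < tol:
                break
        else:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ValidationError(
                f"Cox regression did not converge in {max_iter} iterations "
                f"(largest coefficient: {worst!r})"
            )
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            raise ValidationError("singular information matrix at the optimum") from None
        se = np.sqrt(np.diag(cov))
        z = beta / se
        pvals = 2 * stats.norm.sf(np.abs(z))
        params = pd.DataFrame({
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "p": pvals,
        }, index=pd.Index(names, name="covariate"))
        logger.info("Cox (%s ties): %d patients, %d events, loglik %.3f",
                    self.ties, len(time), int(event.sum()), loglik)
        return CoxResults(params=params, loglik=float(loglik),
                          n=len(time), n_events=int(event.sum()), ties=self.ties)


@dataclass
class CoxResults:
    """Hazard ratios with Wald 95% confidence intervals and p-values."""

    params: pd.DataFrame
    loglik: float
    n: int
    n_events: int
    ties: str

    def hr(self, covariate: str = "group") -> tuple[float, float, float]:
        row = self.params.loc[covariate]
        return float(row["hr"]), float(row["ci_low"]), float(row["ci_high"])

    def summary(self) -> str:
        lines = [
            f"Cox proportional hazards ({self.ties} ties): "
            f"{self.n} patients, {self.n_events} events, "
            f"log partial likelihood {self.loglik:.3f}",
            f"{'covariate':<18}{'HR':>8}{'95% CI':>18}{'p':>10}",
        ]
        for name, row in self.params.iterrows():
            lines.append(
                f"{name:<18}{row['hr']:>8.2f}"
                f"{row['ci_low']:>8.2f} to {row['ci_high']:<7.2f}{row['p']:>10.4g}"
            )
        return "\n".join(lines)


def cox_ph(table: pd.DataFrame, covariates: list[str],
           ties: str = "efron") -> CoxResults:
    """Convenience wrapper: fit a Cox model and return its results."""
    return CoxModel(table, covariates, ties=ties).fit()
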