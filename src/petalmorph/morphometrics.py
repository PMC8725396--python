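"""Quadratic triple-interaction regression along the petal midrib.

The developmental-timing (heterochrony) test fits, by ordinary least
squares with treatment coding,

    y ~ (p + p^2) * stage * species

where y is cell lobeyness CL, log cell area log(CA) or the length-to-width
ratio CLWR, and p is the standardized midrib position PAMR in [0, 1].  The
flower bud and the ancestral-type (basal) species are the reference factor
levels, so the twelve coefficients read as: the basal species' bud curve
(intercept, p, p^2), stage and species main effects, the stage- and
species-specific curve modifications, and the triple interactions
p:stage:species and p^2:stage:species that test whether the developmental
change of the curve itself differs between species — the signature of
delayed differentiation.

Usage follows the Model/Results convention::

    model = QuadraticInteractionModel.from_dataframe(df, response="cl",
                                                     basal_species="A")
    res = model.fit()
    res.summary()
    res.classify_heterochrony(alpha=0.05)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "QuadraticInteractionModel",
    "QuadraticInteractionResults",
    "HeterochronyCall",
    "fit_quadratic_interaction_model",
    "classify_heterochrony",
    "COEFFICIENT_NAMES",
]

COEFFICIENT_NAMES = [
    "intercept", "p", "p2", "stage", "species",
    "p:stage", "p2:stage", "p:species", "p2:species",
    "stage:species", "p:stage:species", "p2:stage:species",
]

RESPONSES = {"cl": "cl", "log_ca": "ca_um2", "clwr": "clwr"}


class DesignError(ValueError):
    """Degenerate or rank-deficient model design."""


@dataclass
class HeterochronyCall:
    """Verdict of the delayed-differentiation test at level alpha.

    ``delayed_differentiation`` requires (i) a significant lobeyness
    gradient along the midrib in buds of the basal species, (ii) a
    significant flattening of that gradient in buds of the derived species
    (p:species interaction of opposite sign), and (iii) a significant
    triple interaction restoring the gradient at maturity.  ``no_delay``:
    (i) holds but the species differences do not.  ``indeterminate``:
    no detectable bud gradient in the basal species.
    """

    verdict: str
    alpha: float
    tests: dict

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"Heterochrony verdict: {self.verdict} (alpha={self.alpha})"]
        for name, t in self.tests.items():
            lines.append(f"  {name}: {t}")
        return "\n".join(lines)


class QuadraticInteractionModel:
    """OLS model of a cell-shape response against midrib position with full
    (p + p^2) x stage x species factorial structure."""

    def __init__(self, endog: np.ndarray, pamr: np.ndarray, stage: np.ndarray,
                 species: np.ndarray, *, response: str = "cl",
                 basal_stage: str = "bud", basal_species: str | None = None):
        endog = np.asarray(endog, dtype=float)
        pamr = np.asarray(pamr, dtype=float)
        stage = np.asarray(stage, dtype=object)
        species = np.asarray(species, dtype=object)
        if not (len(endog) == len(pamr) == len(stage) == len(species)):
            raise ValueError("input arrays must share a length")
        if len(endog) < 13:
            raise DesignError("need >= 13 observations for a 12-coefficient model")
        if np.ptp(pamr) == 0:
            raise DesignError("PAMR is constant; the curve terms are aliased")

        stages = sorted(set(stage))
        specieses = sorted(set(species))
        if len(stages) != 2 or len(specieses) != 2:
            raise DesignError(
                f"need exactly two stages and two species, got {stages} / {specieses}"
            )
        if basal_stage not in stages:
            raise DesignError(f"basal stage {basal_stage!r} not present in data")
        if basal_species is None:
            basal_species = specieses[0]
        if basal_species not in specieses:
            raise DesignError(f"basal species {basal_species!r} not present in data")

        self.response = response
        self.basal_stage = basal_stage
        self.basal_species = basal_species
        self.derived_stage = next(s for s in stages if s != basal_stage)
        self.derived_species = next(s for s in specieses if s != basal_species)

        st = (stage == self.derived_stage).astype(float)  # 1 = non-basal stage
        sp = (species == self.derived_species).astype(float)
        p = pamr
        X = np.column_stack([
            np.ones_like(p), p, p**2, st, sp,
            p * st, p**2 * st, p * sp, p**2 * sp,
            st * sp, p * st * sp, p**2 * st * sp,
        ])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name aliased columns for the error message
            _, r = np.linalg.qr(X)
            aliased = [COEFFICIENT_NAMES[i] for i in range(X.shape[1])
                       if abs(r[i, i]) < 1e-10]
            raise DesignError(f"rank-deficient design; aliased terms: {aliased}")
        self.exog = X
        self.endog = endog
        self.nobs = len(endog)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "cl", *,
                       basal_stage: str = "bud", basal_species: str | None = None,
                       log_area: bool | None = None) -> "QuadraticInteractionModel":
        """Build from a cell-metric table (columns ``species stage pamr`` and
        the response).  ``response='log_ca'`` takes the natural log of the
        ``ca_um2`` column."""
        if response not in RESPONSES:
            raise ValueError(f"response must be one of {sorted(RESPONSES)}")
        col = RESPONSES[response]
        if col not in df.columns:
            raise ValueError(f"metric table lacks column {col!r}")
        y = df[col].to_numpy(dtype=float)
        if response == "log_ca":
            if (y <= 0).any():
                raise ValueError("cell areas must be positive to take logs")
            y = np.log(y)
        return cls(y, df["pamr"].to_numpy(), df["stage"].to_numpy(),
                   df["species"].to_numpy(), response=response,
                   basal_stage=basal_stage, basal_species=basal_species)

    def fit(self) -> "QuadraticInteractionResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return QuadraticInteractionResults(self, res)


class QuadraticInteractionResults:
    """Estimates, standard errors, t and p values of the fitted model."""

    def __init__(self, model: QuadraticInteractionModel, sm_results):
        self.model = model
        self._sm = sm_results
        self.params = pd.Series(sm_results.params, index=COEFFICIENT_NAMES)
        self.bse = pd.Series(sm_results.bse, index=COEFFICIENT_NAMES)
        self.tvalues = pd.Series(sm_results.tvalues, index=COEFFICIENT_NAMES)
        self.pvalues = pd.Series(sm_results.pvalues, index=COEFFICIENT_NAMES)
        self.df_resid = int(sm_results.df_resid)
        self.nobs = int(model.nobs)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": COEFFICIENT_NAMES,
            "estimate": self.params.to_numpy(),
            "se": self.bse.to_numpy(),
            "t": self.tvalues.to_numpy(),
            "p": self.pvalues.to_numpy(),
        })

    def summary(self) -> str:
        m = self.model
        head = (
            f"Quadratic triple-interaction OLS  response={m.response}  "
            f"n={self.nobs}  df_resid={self.df_resid}\n"
            f"reference levels: stage={m.basal_stage}, species={m.basal_species}\n"
        )
        body = self.coefficient_table().to_string(
            index=False, float_format=lambda v: f"{v: .6g}")
        return head + body

    def predict_curve(self, species: str, stage: str, p) -> np.ndarray:
        """Fitted response curve for one (species, stage) at positions p."""
        m = self.model
        if species not in (m.basal_species, m.derived_species):
            raise ValueError(f"unknown species {species!r}")
        if stage not in (m.basal_stage, m.derived_stage):
            raise ValueError(f"unknown stage {stage!r}")
        p = np.asarray(p, dtype=float)
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("p values must lie in [0, 1]")
        st = float(stage == m.derived_stage)
        sp = float(species == m.derived_species)
        X = np.column_stack([
            np.ones_like(p), p, p**2,
            np.full_like(p, st), np.full_like(p, sp),
            p * st, p**2 * st, p * sp, p**2 * sp,
            np.full_like(p, st * sp), p * st * sp, p**2 * st * sp,
        ])
        return X @ self.params.to_numpy()

    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._sm.fittedvalues)

    def triple_interaction_ftest(self):
        """Joint F test of the two triple-interaction terms."""
        R = np.zeros((2, 12))
        R[0, COEFFICIENT_NAMES.index("p:stage:species")] = 1
        R[1, COEFFICIENT_NAMES.index("p2:stage:species")] = 1
        return self._sm.f_test(R)

    def classify_heterochrony(self, alpha: float = 0.05) -> HeterochronyCall:
        return classify_heterochrony(self, alpha)

    def plot(self, ax=None, n_points: int = 101):
        """Fitted curves for the four (species, stage) groups."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        p = np.linspace(0, 1, n_points)
        for sp in (m.basal_species, m.derived_species):
            for st in (m.basal_stage, m.derived_stage):
                ax.plot(p, self.predict_curve(sp, st, p), label=f"{sp} / {st}")
        ax.set_xlabel("PAMR (0 = basal, 1 = apical)")
        ax.set_ylabel(m.response)
        ax.legend()
        return ax


def fit_quadratic_interaction_model(
    df: pd.DataFrame, response: str = "cl", *, basal_stage: str = "bud",
    basal_species: str | None = None,
) -> QuadraticInteractionResults:
    """Functional wrapper over the Model/Results pair."""
    return QuadraticInteractionModel.from_dataframe(
        df, response=response, basal_stage=basal_stage, basal_species=basal_species,
    ).fit()


def _sig(p: float, alpha: float) -> bool:
    return bool(np.isfinite(p) and p <= alpha)


def classify_heterochrony(fit: QuadraticInteractionResults, alpha: float = 0.05) -> HeterochronyCall:
    """Delayed-differentiation verdict from a lobeyness fit.

    The three conditions (see :class:`HeterochronyCall`) are evaluated on
    the fitted coefficients alone, so the verdict is reproducible from the
    fit and alpha.  Non-finite p values (degenerate fits, e.g. a constant
    response) count as non-significant.
    """
    for name in ("p", "p2", "p:species", "p:stage:species"):
        if name not in fit.params.index:
            raise ValueError(f"fit lacks coefficient {name!r}")
    p_lin, p_quad = fit.pvalues["p"], fit.pvalues["p2"]
    basal_gradient = _sig(p_lin, alpha) or _sig(p_quad, alpha)
    grad_sign = np.sign(fit.params["p"]) if _sig(p_lin, alpha) else np.sign(fit.params["p2"])

    flat = fit.params["p:species"]
    flattened = _sig(fit.pvalues["p:species"], alpha) and np.sign(flat) == -grad_sign
    triple = fit.params["p:stage:species"]
    restored = _sig(fit.pvalues["p:stage:species"], alpha) and np.sign(triple) == grad_sign

    tests = {
        "basal_bud_gradient": {
            "t_p": float(fit.tvalues["p"]), "pval_p": float(p_lin),
            "t_p2": float(fit.tvalues["p2"]), "pval_p2": float(p_quad),
            "significant": basal_gradient,
        },
        "derived_bud_flattening": {
            "estimate": float(flat), "t": float(fit.tvalues["p:species"]),
            "pval": float(fit.pvalues["p:species"]), "significant": bool(flattened),
        },
        "maturity_restoration": {
            "estimate": float(triple), "t": float(fit.tvalues["p:stage:species"]),
            "pval": float(fit.pvalues["p:stage:species"]), "significant": bool(restored),
        },
    }
    if not basal_gradient:
        verdict = "indeterminate"
    elif flattened and restored:
        verdict = "delayed_differentiation"
    else:
        verdict = "no_delay"
    return HeterochronyCall(verdict=verdict, alpha=alpha, tests=tests)
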