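"""Response-surface fitting, ANOVA and desirability optimization.

Model
-----
Each response is fit by ordinary least squares on coded units with a
quadratic surface: intercept, linear terms for all factors and square terms
for every 3-level factor.  Two-factor interactions can be requested; they
are added in a fixed lexicographic order and any term that would make the
design matrix rank-deficient (heavily aliased in an 18-run orthogonal
array) is pruned.  The default model carries no interactions: on the
18-run screening table the pure quadratic reproduces the printed
verification predictions and leaves 8 residual degrees of freedom.

ANOVA
-----
Per-factor significance uses partial F-tests: the full model against the
model with every term involving that factor removed.

Desirability
------------
Multi-response optimization composes per-response desirabilities d ∈ [0, 1]
by a weighted geometric mean (Derringer–Suich).  Two shapes are provided:
a larger-is-better ramp between two anchors, and a target-at-limit shape
that rises linearly from a lower anchor to 1 at the limit and falls to 0
beyond it — appropriate when the best protocol should use the full budget
of a response (here: drive the temperature to, but not past, the 50 °C
damage limit).

The optimizer maximizes the composite over the continuous coded cube of
3-level factors crossed with enumeration of 2-level factors, by a dense
coarse scan followed by Nelder–Mead polish from the best scan points plus
seeded random multi-starts.  Ties are broken toward the least energetic
protocol (smallest voltage, then smallest pulse number).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
import statsmodels.api as sm

from .doe import DesignTable, FactorSpec, decode, encode

__all__ = [
    "ResponseSurface",
    "fit_rsm",
    "anova_table",
    "Desirability",
    "larger_is_better",
    "target_at_limit",
    "smaller_is_better",
    "OptimizationResult",
    "optimize_desirability",
]


def _term_names(factors: list[FactorSpec], interactions: list[tuple[int, int]]) -> list[str]:
    names = ["intercept"] + [f.name for f in factors]
    names += [f"{f.name}^2" for f in factors if f.n_levels == 3]
    names += [f"{factors[a].name}:{factors[b].name}" for a, b in interactions]
    return names


def _design_matrix(
    coded: np.ndarray, factors: list[FactorSpec], interactions: list[tuple[int, int]]
) -> np.ndarray:
    c = np.atleast_2d(coded)
    cols = [np.ones(len(c))]
    cols += [c[:, j] for j in range(len(factors))]
    cols += [c[:, j] ** 2 for j, f in enumerate(factors) if f.n_levels == 3]
    cols += [c[:, a] * c[:, b] for a, b in interactions]
    return np.column_stack(cols)


class ResponseSurface:
    """Quadratic response surface on coded units (scikit-learn-style).

    Parameters
    ----------
    factors : list of FactorSpec
    include_interactions : bool
        Request all two-factor interactions, pruned for estimability in a
        fixed lexicographic order (later candidates dropped first).
    active_factors : sequence of str, optional
        Restrict the surface to a subset of factors; the rest contribute no
        terms (used for responses known to be independent of some factors).

    Attributes (after fit)
    ----------------------
    params_ : pd.Series of coefficients by term name
    result_ : statsmodels OLS results
    """

    def __init__(
        self,
        factors: list[FactorSpec],
        include_interactions: bool = False,
        active_factors: tuple[str, ...] | None = None,
    ):
        self.factors = factors
        self.include_interactions = include_interactions
        self.active_factors = active_factors

    def _active(self) -> list[FactorSpec]:
        if self.active_factors is None:
            return self.factors
        return [f for f in self.factors if f.name in self.active_factors]

    def _interaction_list(self, coded: np.ndarray, act: list[FactorSpec]) -> list[tuple[int, int]]:
        if not self.include_interactions:
            return []
        base = _design_matrix(coded, act, [])
        kept: list[tuple[int, int]] = []
        rank = np.linalg.matrix_rank(base)
        for pair in itertools.combinations(range(len(act)), 2):
            trial = kept + [pair]
            M = _design_matrix(coded, act, trial)
            r = np.linalg.matrix_rank(M)
            if r == rank + len(trial) and r < len(coded):
                kept.append(pair)
        return kept

    def fit(self, design: DesignTable, y: np.ndarray) -> "ResponseSurface":
        y = np.asarray(y, dtype=float)
        if len(y) != design.n_runs:
            raise ValueError("response length does not match the design")
        act = self._active()
        cols = [i for i, f in enumerate(self.factors) if f in act]
        coded = design.coded[:, cols]
        self.interactions_ = self._interaction_list(coded, act)
        X = _design_matrix(coded, act, self.interactions_)
        if len(y) < X.shape[1]:
            raise ValueError(
                f"{len(y)} runs cannot estimate {X.shape[1]} model terms"
            )
        self.term_names_ = _term_names(act, self.interactions_)
        self._act_cols = cols
        self.result_ = sm.OLS(y, X).fit()
        self.params_ = pd.Series(self.result_.params, index=self.term_names_)
        return self

    def predict(self, natural: np.ndarray) -> np.ndarray:
        """Predict the response at natural-unit factor settings."""
        coded = encode(natural, self.factors)
        return self.predict_coded(coded)

    def predict_coded(self, coded: np.ndarray) -> np.ndarray:
        act = self._active()
        c = np.atleast_2d(coded)[:, self._act_cols]
        X = _design_matrix(c, act, self.interactions_)
        return X @ self.result_.params

    def get_params(self, deep: bool = True) -> dict:
        return {
            "factors": self.factors,
            "include_interactions": self.include_interactions,
            "active_factors": self.active_factors,
        }

    def set_params(self, **kw) -> "ResponseSurface":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def anova(self) -> pd.DataFrame:
        """Per-factor partial F-tests against the residual (see module docs)."""
        from scipy.stats import f as fdist

        act = self._active()
        X = self.result_.model.exog
        y = self.result_.model.endog
        rows = []
        rss_full = self.result_.ssr
        df_resid = self.result_.df_resid
        for f in act:
            drop = {f.name, f"{f.name}^2"} | {
                t for t in self.term_names_ if ":" in t and f.name in t.split(":")
            }
            keep_idx = [i for i, t in enumerate(self.term_names_) if t not in drop]
            red = sm.OLS(y, X[:, keep_idx]).fit()
            df_num = len(self.term_names_) - len(keep_idx)
            F = ((red.ssr - rss_full) / df_num) / (rss_full / df_resid)
            p = float(fdist.sf(F, df_num, df_resid))
            rows.append((f.name, df_num, F, p))
        return pd.DataFrame(rows, columns=["factor", "df", "F", "p_value"]).set_index("factor")


def fit_rsm(
    design: DesignTable,
    y: np.ndarray,
    include_interactions: bool = False,
    active_factors: tuple[str, ...] | None = None,
) -> ResponseSurface:
    """Fit one response surface to one response column."""
    return ResponseSurface(
        design.factors,
        include_interactions=include_interactions,
        active_factors=active_factors,
    ).fit(design, y)


def anova_table(model: ResponseSurface) -> pd.DataFrame:
    return model.anova()


@dataclass
class Desirability:
    """Per-response desirability d(y) ∈ [0, 1] with an importance weight."""

    kind: str  # "larger", "smaller", "target_at_limit"
    low: float
    high: float
    weight: float = 1.0

    def __call__(self, y):
        y = np.asarray(y, dtype=float)
        span = self.high - self.low
        if self.kind == "larger":
            return np.clip((y - self.low) / span, 0.0, 1.0)
        if self.kind == "smaller":
            return np.clip((self.high - y) / span, 0.0, 1.0)
        if self.kind == "target_at_limit":
            d = np.clip((y - self.low) / span, 0.0, 1.0)
            return np.where(y > self.high, 0.0, d)
        raise ValueError(f"unknown desirability kind {self.kind!r}")


def larger_is_better(low: float, high: float, weight: float = 1.0) -> Desirability:
    """Ramp from 0 at ``low`` to 1 at ``high`` (typically the observed range)."""
    return Desirability("larger", low, high, weight)


def smaller_is_better(low: float, high: float, weight: float = 1.0) -> Desirability:
    """Ramp from 1 at ``low`` to 0 at ``high``."""
    return Desirability("smaller", low, high, weight)


def target_at_limit(low: float, limit: float, weight: float = 1.0) -> Desirability:
    """Rise from 0 at ``low`` to 1 at the limit; 0 beyond it.

    Encodes "use the full budget of this response but never exceed it".
    """
    return Desirability("target_at_limit", low, limit, weight)


@dataclass
class OptimizationResult:
    """Desirability optimum with predicted responses."""

    natural: pd.Series
    coded: np.ndarray
    desirability: float
    predictions: dict[str, float]
    pulse_number_rounded: int | None = None
    n_evaluations: int = 0


def _composite(
    coded: np.ndarray,
    models: dict[str, ResponseSurface],
    desirabilities: dict[str, Desirability],
) -> np.ndarray:
    c = np.atleast_2d(coded)
    total_w = sum(d.weight for d in desirabilities.values())
    log_d = np.zeros(len(c))
    ok = np.ones(len(c), dtype=bool)
    for name, des in desirabilities.items():
        y = models[name].predict_coded(c)
        d = des(y)
        ok &= d > 0
        with np.errstate(divide="ignore"):
            log_d += des.weight * np.log(np.where(d > 0, d, 1.0))
    out = np.where(ok, np.exp(log_d / total_w), 0.0)
    return out


def optimize_desirability(
    models: dict[str, ResponseSurface],
    desirabilities: dict[str, Desirability],
    factors: list[FactorSpec],
    n_starts: int = 64,
    seed: int = 0,
    grid_points: int = 13,
    round_pulses_to: int = 10,
) -> OptimizationResult:
    """Maximize the composite desirability over the factor box.

    2-level factors are enumerated at their two levels; 3-level factors vary
    continuously in coded [−1, 1].  A dense coarse grid scan seeds
    Nelder–Mead polish (the composite has clipping kinks and a hard zero
    beyond the temperature limit, so a simplex method is more reliable than
    gradient descent); seeded random multi-starts guard against grid
    aliasing.  Returns natural-unit settings, predictions of every modelled
    response, and the pulse number rounded to the nearest deliverable
    multiple.
    """
    missing = set(desirabilities) - set(models)
    if missing:
        raise ValueError(f"no model for desirabilities {sorted(missing)}")
    rng = np.random.default_rng(seed)
    cont = [i for i, f in enumerate(factors) if f.n_levels == 3]
    disc = [i for i, f in enumerate(factors) if f.n_levels == 2]
    n_evals = 0

    g = np.linspace(-1.0, 1.0, grid_points)
    cont_grid = np.array(list(itertools.product(*([g] * len(cont)))))

    best: tuple[float, np.ndarray] | None = None
    for combo in itertools.product(*([(-1.0, 1.0)] * len(disc))):
        def embed(z: np.ndarray) -> np.ndarray:
            full = np.zeros(len(factors))
            for k, i in enumerate(disc):
                full[i] = combo[k]
            for k, i in enumerate(cont):
                full[i] = z[k]
            return full

        cc = np.zeros((len(cont_grid), len(factors)))
        for k, i in enumerate(disc):
            cc[:, i] = combo[k]
        for k, i in enumerate(cont):
            cc[:, i] = cont_grid[:, k]
        d = _composite(cc, models, desirabilities)
        n_evals += len(cc)

        starts = [cont_grid[i] for i in np.argsort(d)[::-1][:8]]
        starts += list(rng.uniform(-1.0, 1.0, size=(n_starts, len(cont))))
        for z0 in starts:
            r = minimize(
                lambda z: -_composite(embed(np.clip(z, -1, 1)), models, desirabilities)[0],
                z0,
                method="Nelder-Mead",
                bounds=[(-1.0, 1.0)] * len(cont),
                options=dict(xatol=1e-7, fatol=1e-12, maxiter=4000),
            )
            n_evals += r.nfev
            cand = embed(np.clip(r.x, -1, 1))
            val = float(_composite(cand, models, desirabilities)[0])
            if best is None or val > best[0] + 1e-12:
                best = (val, cand)
            elif abs(val - best[0]) <= 1e-12:
                best = (best[0], _tie_break(best[1], cand, factors))

    if best is None or best[0] <= 0.0:
        raise RuntimeError("composite desirability is zero everywhere searched")

    d_opt, c_opt = best
    nat = decode(c_opt, factors)[0]
    natural = pd.Series(nat, index=[f.name for f in factors])
    predictions = {
        name: float(m.predict_coded(c_opt[None, :])[0]) for name, m in models.items()
    }
    rounded = None
    if "pulse_number" in natural.index and round_pulses_to:
        rounded = int(round_pulses_to * round(natural["pulse_number"] / round_pulses_to))
    return OptimizationResult(
        natural=natural,
        coded=c_opt,
        desirability=d_opt,
        predictions=predictions,
        pulse_number_rounded=rounded,
        n_evaluations=n_evals,
    )


def _tie_break(a: np.ndarray, b: np.ndarray, factors: list[FactorSpec]) -> np.ndarray:
    """Prefer the less energetic of two equally desirable optima."""
    order = ["voltage_V", "pulse_number"]
    names = [f.name for f in factors]
    for key in order:
        if key in names:
            i = names.index(key)
            if abs(a[i] - b[i]) > 1e-9:
                return a if a[i] < b[i] else b
    return a


def main_effects(design: DesignTable, responses: pd.DataFrame, response_cols: list[str]) -> pd.DataFrame:
    """Mean response at each factor level (main-effects / factorial-trend table)."""
    rows = []
    nat = design.natural
    for f in design.factors:
        for lv in f.levels:
            mask = np.isclose(nat[f.name].to_numpy(), lv)
            for rc in response_cols:
                rows.append((f.name, lv, rc, float(responses.loc[mask, rc].mean())))
    return pd.DataFrame(rows, columns=["factor", "level", "response", "mean"])
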