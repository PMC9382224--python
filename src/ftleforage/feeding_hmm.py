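"""Covariate-dependent Markov model of feeding intensity.

With the four behavioural states (non-feeding, light, moderate, heavy)
known a priori from the normalised feeding rates, the hidden-Markov
likelihood factorises and the transition structure can be fit directly:
for each origin state, a multinomial logit of the next state on the FTLE
value at the origin dive (supervised learning).  The implied transition
matrix Gamma(x) at any FTLE value x yields stationary state probabilities
pi(x) solving pi Gamma = pi, and the estimated overall feeding rate

    rate(x) = sum_state pi_state(x) * feeding_rate_state

with the non-feeding state contributing rate 0.  Confidence curves come
from evaluating the same quantities at the coefficient interval endpoints
(beta +/- 1.96 SE).

Conventions: the reference category of each origin's multinomial logit is
the self-transition (diagonal); the FTLE covariate governing a transition
is the value at the origin dive; individuals' sequences are independent
(no cross-individual transitions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .biologging import STATES

__all__ = [
    "TransitionModel",
    "StationaryCurve",
    "fit_transition_model",
    "transition_matrix_from_beta",
    "transition_matrix",
    "stationary_probabilities",
    "weighted_quantile",
    "weighted_state_feeding_rates",
    "estimate_feeding_rate_curve",
    "expected_rate_from_probs",
    "FTLE_GRID_RANGE",
]

#: FTLE range (day^-1) over which the stationary curve is evaluated
FTLE_GRID_RANGE = (-1.25, 1.5)

_NEVER_OBSERVED_LOGIT = -30.0  # effectively probability zero


def transition_matrix_from_beta(beta: np.ndarray, x: float) -> np.ndarray:
    """Row-wise softmax transition matrix Gamma(x) from logit coefficients.

    ``beta`` has shape (S, S, 2): intercept and FTLE slope of the logit of
    moving i -> j relative to staying in i (the diagonal is the reference
    and is ignored).
    """
    beta = np.asarray(beta, dtype=float)
    S = beta.shape[0]
    logits = beta[:, :, 0] + beta[:, :, 1] * float(x)
    np.fill_diagonal(logits, 0.0)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TransitionModel:
    """Per-origin-state multinomial-logit transition model on FTLE.

    Fitted attributes (after :meth:`fit`): ``beta_`` and ``se_`` of shape
    (S, S, 2) with the diagonal fixed at 0 (reference category), ``cov_``
    (per-origin coefficient covariance), ``n_transitions_``.
    """

    n_states: int = 4
    state_labels: tuple = dc_field(default=None)

    def __post_init__(self):
        if self.state_labels is None:
            self.state_labels = (
                tuple(STATES) if self.n_states == 4
                else tuple(f"state_{i}" for i in range(self.n_states))
            )

    # -- fitting ----------------------------------------------------------
    def fit(self, dives: pd.DataFrame, state_col: str = "state",
            covariate_col: str = "ftle", group_col: str = "individual_id"):
        """Fit from ordered, state-labelled dives with an FTLE covariate.

        Transitions are formed within each individual only; pairs whose
        origin covariate is missing are dropped.  An origin state with no
        outgoing transitions is an error naming the state.
        """
        import statsmodels.api as sm

        S = self.n_states
        labels = list(self.state_labels)
        origins, nexts, xs = [], [], []
        for _, grp in dives.groupby(group_col, sort=False):
            st = pd.Categorical(grp[state_col], categories=labels).codes
            x = np.asarray(grp[covariate_col], dtype=float)
            o, nx, xv = st[:-1], st[1:], x[:-1]
            keep = (o >= 0) & (nx >= 0) & np.isfinite(xv)
            origins.append(o[keep])
            nexts.append(nx[keep])
            xs.append(xv[keep])
        origins = np.concatenate(origins)
        nexts = np.concatenate(nexts)
        xs = np.concatenate(xs)

        beta = np.zeros((S, S, 2))
        se = np.full((S, S, 2), np.nan)
        covs = [None] * S
        for i in range(S):
            sel = origins == i
            if not sel.any():
                raise ValueError(
                    f"origin state {labels[i]!r} has zero outgoing transitions"
                )
            nx = nexts[sel]
            x = xs[sel]
            # order categories with the self-transition first => reference
            order = [i] + [j for j in range(S) if j != i]
            observed = [j for j in order if (nx == j).any()]
            recode = {j: k for k, j in enumerate(observed)}
            endog = np.array([recode[j] for j in nx])
            exog = np.column_stack([np.ones_like(x), x])
            unobserved = [j for j in order if j not in observed]
            for j in unobserved:
                beta[i, j] = (_NEVER_OBSERVED_LOGIT, 0.0)
            if len(observed) == 1:
                continue  # only self-transitions seen; all others ~impossible
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MNLogit(endog, exog).fit(disp=0, maxiter=200)
            params = np.asarray(res.params)          # (2, n_obs-1)
            bse = np.asarray(res.bse)
            for k, j in enumerate(observed[1:]):
                beta[i, j] = params[:, k]
                se[i, j] = bse[:, k]
            covs[i] = np.asarray(res.cov_params())
        self.beta_ = beta
        self.se_ = se
        self.cov_ = covs
        self.n_transitions_ = int(origins.size)
        return self

    # -- prediction -------------------------------------------------------
    def transition_matrix(self, x: float) -> np.ndarray:
        return transition_matrix_from_beta(self.beta_, x)

    def stationary(self, x: float) -> np.ndarray:
        return stationary_probabilities(self.transition_matrix(x))


def fit_transition_model(dives: pd.DataFrame, n_states: int = 4,
                         **kw) -> TransitionModel:
    """Functional wrapper over :class:`TransitionModel`."""
    labels = kw.pop("state_labels", None)
    return TransitionModel(n_states=n_states, state_labels=labels).fit(dives, **kw)


def transition_matrix(model, x: float) -> np.ndarray:
    """Gamma(x) for a fitted model or a raw (S, S, 2) coefficient array."""
    if isinstance(model, TransitionModel):
        return model.transition_matrix(x)
    return transition_matrix_from_beta(np.asarray(model), x)


# ---------------------------------------------------------------------------
# stationary distribution
# ---------------------------------------------------------------------------

def _is_irreducible(gamma: np.ndarray, tol: float = 1e-12) -> bool:
    adj = gamma > tol
    n = adj.shape[0]
    reach = adj.copy()
    for _ in range(n):
        reach = reach | (reach @ adj)
    return bool(reach.all())


def stationary_probabilities(gamma: np.ndarray) -> np.ndarray:
    """Solve pi Gamma = pi, sum(pi) = 1, for a row-stochastic Gamma.

    Uses the constrained linear system (replace one balance equation with
    the normalisation).  A reducible chain is rejected with a diagnosis.
    """
    gamma = np.asarray(gamma, dtype=float)
    n = gamma.shape[0]
    if gamma.shape != (n, n):
        raise ValueError("gamma must be square")
    rows = gamma.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-8):
        raise ValueError(f"gamma rows must sum to 1 (got {rows})")
    if not _is_irreducible(gamma):
        raise ValueError(
            "transition matrix is reducible: some state cannot reach some "
            "other state; the stationary distribution is not unique"
        )
    A = np.vstack([(gamma.T - np.eye(n))[:-1], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


# ---------------------------------------------------------------------------
# weighted feeding rates
# ---------------------------------------------------------------------------

def weighted_quantile(values, weights, q: float) -> float:
    """Inverted-CDF weighted quantile: smallest value with CDF >= q."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    cw = cw / cw[-1]
    return float(v[np.searchsorted(cw, q - 1e-12)])


def weighted_state_feeding_rates(rates, weights) -> tuple[float, float, float]:
    """Mean feeding rate of the light/moderate/heavy segments.

    The pooled, individually weighted feeding-rate distribution is cut at
    its weighted 25th and 75th percentiles; the weighted mean of each
    segment (light: rate <= q25; moderate: q25 < rate <= q75; heavy:
    rate > q75) is returned in lunges per hour.
    """
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    q25 = weighted_quantile(rates, weights, 0.25)
    q75 = weighted_quantile(rates, weights, 0.75)
    segs = [rates <= q25, (rates > q25) & (rates <= q75), rates > q75]
    out = []
    for name, seg in zip(("light", "moderate", "heavy"), segs):
        if not seg.any():
            raise ValueError(f"empty {name} feeding segment")
        out.append(float(np.average(rates[seg], weights=weights[seg])))
    return tuple(out)


def expected_rate_from_probs(probs, state_rates) -> float:
    """Overall rate from stationary probabilities and the 3 feeding-state rates.

    ``probs`` is (non-feeding, light, moderate, heavy); the non-feeding
    state contributes rate 0.
    """
    probs = np.asarray(probs, dtype=float)
    rates = np.concatenate([[0.0], np.asarray(state_rates, dtype=float)])
    return float(probs @ rates)


# ---------------------------------------------------------------------------
# stationary curve
# ---------------------------------------------------------------------------

@dataclass
class StationaryCurve:
    """Stationary state probabilities and estimated rate over an FTLE grid."""

    x: np.ndarray                  # FTLE grid, day^-1
    probabilities: np.ndarray      # (len(x), S)
    rate: np.ndarray               # lunges h^-1
    rate_lower: np.ndarray
    rate_upper: np.ndarray
    state_rates: tuple
    extrapolated: np.ndarray       # outside the fitted FTLE range
    state_labels: tuple

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"ftle": self.x})
        for k, lab in enumerate(self.state_labels):
            df[f"pi_{lab}"] = self.probabilities[:, k]
        df["rate"] = self.rate
        df["rate_lower"] = self.rate_lower
        df["rate_upper"] = self.rate_upper
        df["extrapolated"] = self.extrapolated
        return df


def estimate_feeding_rate_curve(
    model: TransitionModel,
    state_rates,
    x_grid=None,
) -> StationaryCurve:
    """Estimated overall feeding rate as a function of FTLE.

    rate(x) = sum_state pi_state(x) * rate_state, with the non-feeding
    state's rate 0; lower/upper curves evaluate the same formula with every
    coefficient at beta -/+ 1.96 SE.  Grid values outside the standard
    evaluation range are computed but flagged as extrapolation.
    """
    if x_grid is None:
        x_grid = np.arange(FTLE_GRID_RANGE[0], FTLE_GRID_RANGE[1] + 1e-9, 0.01)
    x_grid = np.asarray(x_grid, dtype=float)
    state_rates = tuple(float(r) for r in state_rates)
    if len(state_rates) != model.n_states - 1:
        raise ValueError("need one rate per feeding state")
    if any(r <= 0 for r in state_rates) or list(state_rates) != sorted(state_rates):
        raise ValueError("state rates must be positive and ordered")

    se = np.where(np.isfinite(model.se_), model.se_, 0.0)
    variants = {
        "mid": model.beta_,
        "lo": model.beta_ - 1.96 * se,
        "hi": model.beta_ + 1.96 * se,
    }
    curves = {}
    probs_mid = None
    for name, beta in variants.items():
        r = np.empty(x_grid.size)
        probs = np.empty((x_grid.size, model.n_states))
        for k, x in enumerate(x_grid):
            pi = stationary_probabilities(transition_matrix_from_beta(beta, x))
            probs[k] = pi
            r[k] = expected_rate_from_probs(pi, state_rates)
        curves[name] = r
        if name == "mid":
            probs_mid = probs
    lo = np.minimum(np.minimum(curves["lo"], curves["hi"]), curves["mid"])
    hi = np.maximum(np.maximum(curves["lo"], curves["hi"]), curves["mid"])
    extrap = (x_grid < FTLE_GRID_RANGE[0]) | (x_grid > FTLE_GRID_RANGE[1])
    return StationaryCurve(
        x=x_grid,
        probabilities=probs_mid,
        rate=curves["mid"],
        rate_lower=lo,
        rate_upper=hi,
        state_rates=state_rates,
        extrapolated=extrap,
        state_labels=tuple(model.state_labels),
    )
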