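"""All-subsets model enumeration, WAIC ranking, and inclusion rates.

Following the collinearity screen, every non-empty combination of the
retained variable-level terms is a candidate model (the categorical habitat
layer enters or leaves as one block of indicator columns).  Candidates are
ranked by the Watanabe-Akaike information criterion,

    WAIC = -2 (lppd - p_waic),

where lppd is the log pointwise predictive density and p_waic the
variance-based effective parameter count, both computed from the posterior
pointwise log-likelihood matrix.  The most supported model is the one with
the lowest WAIC; "inclusion rates" summarize how often each variable
appears in the top 5% of candidates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .choices import ChoiceData
from .errors import InsufficientDataError, InvalidConfigError
from .inference import FitResult, McmcConfig, fit_individual

#: Cheaper sampler budget for the all-subsets sweep; the winner is refit at
#: the full budget.  WAIC ordering is robust to this level of Monte-Carlo error.
CANDIDATE_BUDGET = {"n_chains": 2, "n_draws": 600, "n_burnin": 150}


@dataclass(frozen=True)
class CandidateModel:
    """A subset of variable-level terms ('habitat' is a single block)."""

    variables: tuple[str, ...]

    @property
    def model_id(self) -> str:
        return "+".join(self.variables)

    def n_params(self, coding) -> int:
        return len(coding.columns_for(list(self.variables)))


@dataclass
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise: np.ndarray  # per-set (lppd_i, p_waic_i) contributions, shape (n_sets, 2)


def enumerate_candidates(variables: list[str], cap: int = 16) -> list[CandidateModel]:
    """All 2^V - 1 non-empty subsets of variable-level terms, binary-counter order."""
    V = len(variables)
    if V < 1:
        raise InvalidConfigError("need at least one variable to enumerate")
    if V > cap:
        raise InvalidConfigError(
            f"{V} variables imply {2**V - 1} candidates (cap {cap}); "
            "restrict the candidate list explicitly or raise the cap"
        )
    out = []
    for mask in range(1, 2**V):
        out.append(CandidateModel(tuple(v for i, v in enumerate(variables) if mask >> i & 1)))
    return out


def compute_waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from a (n_draws, n_sets) pointwise log-likelihood matrix."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[1] < 1:
        raise InvalidConfigError("pointwise log-likelihood must be (n_draws, n_sets)")
    S = ll.shape[0]
    if S < 2:
        warnings.warn("single posterior draw: p_waic = 0", stacklevel=2)
        lppd_i = ll[0]
        p_i = np.zeros_like(lppd_i)
    else:
        lppd_i = logsumexp(ll, axis=0) - math.log(S)
        p_i = ll.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WaicResult(
        lppd=lppd,
        p_waic=p_waic,
        waic=-2.0 * (lppd - p_waic),
        pointwise=np.column_stack([lppd_i, p_i]),
    )


def fit_candidates(
    data: ChoiceData,
    candidates: list[CandidateModel] | None = None,
    config: McmcConfig | None = None,
    cap: int = 16,
) -> list[tuple[CandidateModel, WaicResult, FitResult]]:
    """Fit every candidate with the reduced sampler budget and score by WAIC."""
    if data.coding is None:
        raise InsufficientDataError("candidate fitting requires a coding manifest")
    if candidates is None:
        candidates = enumerate_candidates(data.coding.variables, cap=cap)
    base = config or McmcConfig()
    cheap = base.replace(**CANDIDATE_BUDGET)
    out = []
    for i, cand in enumerate(candidates):
        sub = data.subset_variables(list(cand.variables))
        fit = fit_individual(sub, cheap.replace(seed=base.seed + 1000 + i))
        out.append((cand, compute_waic(fit.pointwise), fit))
    return out


def rank_models(
    fits: list[tuple[CandidateModel, WaicResult]] | list[tuple[CandidateModel, WaicResult, FitResult]],
    coding=None,
) -> pd.DataFrame:
    """Rank candidates by ascending WAIC.

    Ties break toward fewer parameters, then lexical variable order.  The
    returned frame carries model_id, variables, n_params, lppd, p_waic,
    waic, and 1-based rank.
    """
    if not fits:
        raise InsufficientDataError("no fitted candidates to rank")
    rows = []
    for tup in fits:
        cand, waic = tup[0], tup[1]
        n_params = cand.n_params(coding) if coding is not None else len(cand.variables)
        rows.append(
            {
                "model_id": cand.model_id,
                "variables": ",".join(cand.variables),
                "n_params": n_params,
                "lppd": waic.lppd,
                "p_waic": waic.p_waic,
                "waic": waic.waic,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["waic", "n_params", "variables"], kind="stable", ignore_index=True
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def inclusion_rates(ranked: pd.DataFrame, top_fraction: float = 0.05) -> pd.DataFrame:
    """Fraction of the top-ranked models containing each variable.

    The top set holds ceil(top_fraction * n_models) models.
    """
    if not 0 < top_fraction <= 1:
        raise InvalidConfigError("top_fraction must be in (0, 1]")
    if len(ranked) == 0:
        raise InsufficientDataError("empty ranking")
    n_top = math.ceil(top_fraction * len(ranked))
    top = ranked.nsmallest(n_top, "rank")
    all_vars = sorted({v for s in ranked["variables"] for v in s.split(",")})
    rates = {
        v: float(np.mean([v in s.split(",") for s in top["variables"]])) for v in all_vars
    }
    return pd.DataFrame({"variable": list(rates), "rate": list(rates.values())})
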