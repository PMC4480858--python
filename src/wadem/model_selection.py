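"""AICc candidate-set machinery: enumeration, ranking and retention,
Akaike weights, model-averaged coefficients and unconditional standard
errors, and per-term importance.

All candidates in a set share one random structure and are fitted by ML on
the identical case set (complete cases of the union of their terms), so
their AICc values are comparable. Models are retained while
``delta AICc < 4`` (strict); Akaike weights are renormalized over the
retained set. A term's model-averaged coefficient uses weights renormalized
over the models containing it; its unconditional standard error follows the
Burnham-Anderson formula ``sqrt(sum w (se^2 + (beta - avg)^2))``; its
importance is the summed retained weight of the containing models.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math

import numpy as np
import pandas as pd

from .formula import base_columns
from .mixed_models import FitError, LmmFit, LmmSpec, SmootherSpec, fit_lmm

DELTA_MAX = 4.0

# the one interaction the candidate families include without both mains
MARGINALITY_EXCEPTIONS = frozenset({"depth_use*depth"})


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: ``-2 logL + 2K + 2K(K+1)/(n-K-1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, K={k} (need n > K + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def check_marginality(terms: tuple[str, ...],
                      exceptions: frozenset[str] = MARGINALITY_EXCEPTIONS) -> str | None:
    """Return the offending requirement, or None if the model is well-formed."""
    present = set(terms)
    for t in terms:
        if t in exceptions:
            continue
        if t.endswith("^2") or "*" in t:
            for main in base_columns(t):
                if main not in present:
                    return f"{t} requires main effect {main}"
    return None


@dataclasses.dataclass
class CandidateSet:
    """Candidate model list for one response, sharing a random structure."""

    response: str
    models: list[tuple[str, ...]]
    random_intercept: str | None = None
    smoother: SmootherSpec | None = None
    criterion: str = "ML"

    def __post_init__(self):
        self.models = [tuple(m) for m in self.models]

    @property
    def term_universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.models:
            for t in m:
                seen.setdefault(t)
        return list(seen)


def build_candidate_set(
    response: str,
    term_universe: list[str],
    max_terms: int = 6,
    explicit_models: list[tuple[str, ...]] | None = None,
    random_intercept: str | None = None,
    smoother: SmootherSpec | None = None,
    marginality: bool = True,
    exceptions: frozenset[str] = MARGINALITY_EXCEPTIONS,
) -> CandidateSet:
    """Enumerate all marginality-respecting subsets of the term universe with
    at most ``max_terms`` terms (including the intercept-only model), or pass
    an explicit model list through after validating it."""
    if explicit_models is not None:
        for m in explicit_models:
            if marginality:
                bad = check_marginality(tuple(m), exceptions)
                if bad:
                    raise ValueError(f"explicit model {m} violates marginality: {bad}")
        models = [tuple(m) for m in explicit_models]
    else:
        if not term_universe:
            raise ValueError("empty term universe")
        models = []
        for r in range(0, max_terms + 1):
            for combo in itertools.combinations(term_universe, r):
                if marginality and check_marginality(combo, exceptions):
                    continue
                models.append(combo)
    return CandidateSet(response, models, random_intercept, smoother)


@dataclasses.dataclass
class RankedModel:
    terms: tuple[str, ...]
    fit: LmmFit
    k: int
    aicc: float
    delta: float = math.nan
    weight: float = math.nan


@dataclasses.dataclass
class AveragedModel:
    """Model-averaging product: ranked retained fits plus per-term summaries."""

    response: str
    retained: list[RankedModel]
    n_candidates: int
    term_table: pd.DataFrame  # index: term; columns: n_models, avg_pe, se, importance
    r2: float
    case_index: pd.Index

    def predict(self, table: pd.DataFrame, include_random: bool = True) -> np.ndarray:
        """Retained-weight average of the per-model predictions."""
        out = np.zeros(len(table))
        for rm in self.retained:
            out += rm.weight * rm.fit.predict(table, include_random=include_random)
        return out

    def coef(self, term: str) -> float:
        return float(self.term_table.loc[term, "avg_pe"])

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "n_candidates": self.n_candidates,
            "r2": self.r2,
            "models": [
                {
                    "terms": list(rm.terms),
                    "K": rm.k,
                    "AICc": rm.aicc,
                    "delta_AICc": rm.delta,
                    "weight": rm.weight,
                }
                for rm in self.retained
            ],
            "terms": {
                t: {
                    "n_models": int(row["n_models"]),
                    "avg_pe": row["avg_pe"],
                    "se": row["se"],
                    "importance": row["importance"],
                }
                for t, row in self.term_table.iterrows()
            },
        }


def rank_and_retain(fits: list[LmmFit], delta_max: float = DELTA_MAX) -> list[RankedModel]:
    """Rank fits by AICc, keep ``delta < delta_max`` (strict), attach weights.

    Ties in AICc break on smaller K, then lexicographic term order, for
    determinism.
    """
    if not fits:
        raise ValueError("no fits to rank")
    ranked = [
        RankedModel(terms=f.spec.fixed_terms, fit=f, k=f.k_params,
                    aicc=aicc(f.loglik, f.k_params, f.n))
        for f in fits
    ]
    ranked.sort(key=lambda rm: (rm.aicc, rm.k, rm.terms))
    best = ranked[0].aicc
    retained = []
    for rm in ranked:
        rm.delta = rm.aicc - best
        if rm.delta < delta_max:
            retained.append(rm)
    wsum = sum(math.exp(-rm.delta / 2.0) for rm in retained)
    for rm in retained:
        rm.weight = math.exp(-rm.delta / 2.0) / wsum
    return retained


def model_average(retained: list[RankedModel], term: str) -> tuple[float, float, float]:
    """(Avg PE, unconditional SE, importance) for one term over retained models."""
    containing = [rm for rm in retained if term in rm.terms or term == "intercept"]
    if not containing:
        raise ValueError(f"term {term!r} absent from every retained model")
    w = np.array([rm.weight for rm in containing])
    importance = float(w.sum())
    w_norm = w / w.sum()
    betas = np.array([rm.fit.coef[term] for rm in containing])
    ses = np.array([rm.fit.se[term] for rm in containing])
    avg = float(w_norm @ betas)
    se = float(np.sqrt(w_norm @ (ses**2 + (betas - avg) ** 2)))
    return avg, se, importance


def fit_candidate_set(
    table: pd.DataFrame,
    cset: CandidateSet,
    smoother_coords: tuple[str, str] = ("x_m", "y_m"),
    delta_max: float = DELTA_MAX,
) -> AveragedModel:
    """Fit every candidate on the identical case set and average.

    The case set is the complete cases of the union of all candidate terms
    (plus the response and random-structure columns), so AICc values are
    comparable across candidates.
    """
    cols = {cset.response}
    for t in cset.term_universe:
        cols.update(base_columns(t))
    if cset.random_intercept:
        cols.add(cset.random_intercept)
    if cset.smoother is not None:
        cols.update(smoother_coords)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"modeling table lacks columns {sorted(missing)}")
    keep = np.ones(len(table), dtype=bool)
    for c in cols:
        v = table[c]
        keep &= v.notna().to_numpy()
        if np.issubdtype(v.dtype, np.number):
            keep &= np.isfinite(v.to_numpy(float))
    data = table.loc[keep]

    fits = []
    for terms in cset.models:
        spec = LmmSpec(
            response=cset.response,
            fixed_terms=terms,
            random_intercept=cset.random_intercept,
            smoother=cset.smoother,
            smoother_coords=smoother_coords,
            criterion=cset.criterion,
        )
        try:
            fits.append(fit_lmm(data, spec))
        except FitError:
            continue  # singular candidates drop out of the set
    if not fits:
        raise FitError("no candidate model could be fitted")
    retained = rank_and_retain(fits, delta_max)

    universe = ["intercept"] + cset.term_universe
    n_containing = {
        t: (len(cset.models) if t == "intercept" else sum(t in m for m in cset.models))
        for t in universe
    }
    rows = {}
    for t in universe:
        if t != "intercept" and not any(t in rm.terms for rm in retained):
            continue
        avg, se, imp = model_average(retained, t)
        rows[t] = {"n_models": n_containing[t], "avg_pe": avg, "se": se, "importance": imp}
    term_table = pd.DataFrame.from_dict(rows, orient="index")

    y = data[cset.response].to_numpy(float)
    pred = np.zeros(len(data))
    for rm in retained:
        pred += rm.weight * rm.fit.predict(data)
    ok = np.isfinite(y) & np.isfinite(pred)
    if ok.sum() >= 3 and np.std(y[ok]) > 0 and np.std(pred[ok]) > 0:
        r2 = float(np.corrcoef(y[ok], pred[ok])[0, 1] ** 2)
    else:
        r2 = math.nan
    return AveragedModel(
        response=cset.response,
        retained=retained,
        n_candidates=len(cset.models),
        term_table=term_table,
        r2=r2,
        case_index=data.index,
    )


# ---------------------------------------------------------------------------
# Reporting


def render_table(avg: AveragedModel, path) -> None:
    """Write the ranking-then-variables report layout to CSV.

    Model rows (terms, K, AICc, delta, weight; R2 on the best row) are
    followed by variable rows (Variable, N, Avg PE, SE, Importance).
    """
    lines = ["model,K,AICc,dAICc,weight,R2"]
    for i, rm in enumerate(avg.retained):
        terms = " + ".join(rm.terms) if rm.terms else "(intercept only)"
        r2 = f"{avg.r2:.3f}" if i == 0 and np.isfinite(avg.r2) else ""
        lines.append(f'"{terms}",{rm.k},{rm.aicc:.2f},{rm.delta:.2f},{rm.weight:.3f},{r2}')
    lines.append("")
    lines.append("variable,N,avg_pe,se,importance")
    for t, row in avg.term_table.iterrows():
        lines.append(
            f"{t},{int(row['n_models'])},{row['avg_pe']:.6g},{row['se']:.6g},"
            f"{row['importance']:.3f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def save_averaged_model(avg: AveragedModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(avg.to_dict(), fh, indent=1)
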