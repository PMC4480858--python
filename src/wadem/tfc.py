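"""Temporal foraging conditions: the daily patch-quality chain.

Stage 1 models each species' daily mean resource *use* (depth, recession
rate, days-since-drydown at occupied cells) as a function of landscape
*availability* (means and SDs of the same covariates over the day's suitable
cells), with a random month intercept — the functional response of habitat
selection to a moving resource gradient. Stage 2 models daily flock and
individual abundance from the used resource levels, availability
heterogeneity, and the dry-to-wet reversal fraction. Chained, the two stages
turn a day's hydrology into a predicted abundance index: availability →
predicted use → predicted abundance (back-transformed).

Count responses are fourth-root transformed toward normality; stork flock
counts are inverse fourth-root transformed (many single-flock days), and the
reporting layer re-inverts the sign so that a larger index always means more
birds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .model_selection import AveragedModel, CandidateSet, fit_candidate_set

MIN_DAYS = 30

RESOURCES = ("depth", "recess", "dsd")


# ---------------------------------------------------------------------------
# Transforms


def transform(value, tag: str):
    """Normality transforms for count responses (vectorized)."""
    v = np.asarray(value, dtype=float)
    if tag == "identity":
        return v if v.shape else float(v)
    if tag == "fourth_root":
        if np.any(v < 0):
            raise ValueError("fourth_root requires value >= 0")
        out = v**0.25
    elif tag == "inv_fourth_root":
        if np.any(v <= 0):
            raise ValueError("inv_fourth_root requires value > 0")
        out = v**-0.25
    elif tag == "inv_square_root":
        if np.any(v <= 0):
            raise ValueError("inv_square_root requires value > 0")
        out = v**-0.5
    else:
        raise ValueError(f"unknown transform {tag!r}")
    return out if out.shape else float(out)


def inverse_transform(value, tag: str):
    v = np.asarray(value, dtype=float)
    if tag == "identity":
        out = v
    elif tag == "fourth_root":
        out = v**4
    elif tag == "inv_fourth_root":
        with np.errstate(divide="ignore"):
            out = v**-4.0
    elif tag == "inv_square_root":
        with np.errstate(divide="ignore"):
            out = v**-2.0
    else:
        raise ValueError(f"unknown transform {tag!r}")
    return out if out.shape else float(out)


def decreasing_transform(tag: str) -> bool:
    """True for transforms that reverse ordering (inverse roots)."""
    return tag in {"inv_fourth_root", "inv_square_root"}


def abundance_transform(species: str, response: str) -> str:
    """Species/response transform rule for the daily abundance models."""
    if species == "stork" and response == "flock":
        return "inv_fourth_root"
    return "fourth_root"


# ---------------------------------------------------------------------------
# Candidate families

# Stage-1 availability-side term families per resource response. Squares and
# interactions obey marginality except the depth-selection interaction
# (depth_use*depth), which enters the DSD response on its own.
SELECTION_UNIVERSE: dict[str, list[str]] = {
    "depth": ["depth", "depth_sd", "depth^2", "recess", "recess_sd", "dsd", "dsd_sd",
              "depth*recess", "recess*dsd"],
    "recess": ["recess", "recess_sd", "recess^2", "depth", "depth_sd", "dsd", "dsd_sd",
               "depth*recess", "recess*dsd"],
    "dsd": ["dsd", "dsd_sd", "dsd^2", "depth", "depth_sd", "depth^2", "recess",
            "depth*dsd", "recess*dsd", "depth_use*depth"],
}

SELECTION_MODELS: dict[str, list[tuple[str, ...]]] = {
    "depth": [
        (),
        ("depth",),
        ("depth", "depth_sd"),
        ("depth", "depth^2"),
        ("depth", "depth_sd", "depth^2"),
        ("depth", "depth_sd", "depth^2", "recess"),
        ("depth", "depth_sd", "depth^2", "recess", "dsd"),
        ("depth", "recess"),
        ("depth", "recess", "depth*recess"),
        ("depth", "depth_sd", "recess", "recess*dsd", "dsd"),
        ("depth", "dsd", "dsd_sd"),
        ("depth", "depth_sd", "dsd", "recess", "recess*dsd"),
    ],
    "recess": [
        (),
        ("recess",),
        ("recess", "recess_sd"),
        ("recess", "recess^2"),
        ("recess", "recess_sd", "recess^2"),
        ("recess", "recess_sd", "depth_sd"),
        ("recess", "recess_sd", "depth", "depth*recess"),
        ("recess", "recess_sd", "depth_sd", "depth", "depth*recess"),
        ("recess", "depth", "depth*recess"),
        ("recess", "recess_sd", "dsd", "recess*dsd"),
    ],
    "dsd": [
        (),
        ("dsd",),
        ("dsd", "dsd_sd"),
        ("dsd", "dsd^2"),
        ("dsd", "dsd_sd", "depth"),
        ("dsd", "dsd_sd", "depth", "depth^2"),
        ("dsd", "dsd_sd", "depth", "depth^2", "depth_use*depth"),
        ("dsd", "dsd_sd", "depth", "depth^2", "depth_use*depth", "depth*dsd"),
        ("dsd", "dsd_sd", "depth", "recess", "recess*dsd"),
        ("dsd", "depth", "depth_use*depth"),
    ],
}

ABUNDANCE_UNIVERSE = [
    "depth_use", "depth_use^2", "depth_sd", "depth",
    "recess_use", "recess_use^2", "recess_sd",
    "dsd_use", "dsd_use^2", "dsd_sd",
    "reversal", "depth_use*depth",
]

ABUNDANCE_MODELS: list[tuple[str, ...]] = [
    (),
    ("depth_use",),
    ("depth_use", "depth_use^2"),
    ("depth_use", "depth_use^2", "depth_sd"),
    ("depth_use", "depth_use^2", "depth_sd", "reversal"),
    ("depth_use", "depth_sd", "depth", "depth_use*depth"),
    ("depth_use", "depth_sd", "depth", "depth_use*depth", "reversal"),
    ("recess_use",),
    ("recess_use", "recess_use^2"),
    ("recess_use", "recess_use^2", "recess_sd"),
    ("recess_use", "recess_use^2", "recess_sd", "reversal"),
    ("dsd_use",),
    ("dsd_use", "dsd_use^2"),
    ("dsd_use", "dsd_sd"),
    ("dsd_use", "depth", "depth_sd"),
    ("dsd_use", "depth", "depth^2", "depth_sd"),
    ("dsd_use", "depth", "depth^2", "depth_sd", "reversal"),
    ("dsd_use", "dsd_use^2", "dsd_sd"),
    ("dsd_use", "dsd_use^2", "dsd_sd", "reversal"),
    ("dsd_use", "dsd_sd", "depth_sd", "reversal"),
    ("depth_use", "dsd_use", "depth_sd", "dsd_sd", "reversal"),
    ("depth_use", "depth_use^2", "dsd_use", "dsd_use^2", "depth_sd", "dsd_sd"),
    ("reversal",),
]


@dataclasses.dataclass
class SelectionModelSet:
    """Stage-1 averaged model for one species x resource."""

    species: str
    resource: str
    averaged: AveragedModel
    training_range: pd.DataFrame  # per predictor column: min, max


@dataclasses.dataclass
class AbundanceModelSet:
    """Stage-2 averaged model for one species x {flock, individual}."""

    species: str
    response: str  # "flock" | "individual"
    transform_tag: str
    averaged: AveragedModel
    training_range: pd.DataFrame


@dataclasses.dataclass
class TfcPrediction:
    """Daily patch-quality prediction on the original count scale."""

    date: object
    species: str
    predicted_use: dict[str, float]
    flock: float
    individual: float
    extrapolated: bool


def _species_days(records: pd.DataFrame, species: str) -> pd.DataFrame:
    sub = records[records["species"] == species].copy()
    sub = sub[sub["flock_count"] >= 1]
    return sub


def _train_range(table: pd.DataFrame, columns: set[str]) -> pd.DataFrame:
    cols = sorted(c for c in columns if c in table.columns)
    return pd.DataFrame({"min": table[cols].min(), "max": table[cols].max()})


def fit_selection(
    records: pd.DataFrame,
    species: str,
    resource: str,
    models: list[tuple[str, ...]] | None = None,
    random_intercept: str | None = "month",
) -> SelectionModelSet:
    """Fit and average the stage-1 use-vs-availability candidates.

    Response is the daily mean use of ``resource`` on days with at least one
    occupied available cell; candidates carry a random month intercept.
    """
    if resource not in RESOURCES:
        raise ValueError(f"unknown resource {resource!r}")
    sub = _species_days(records, species)
    if len(sub) < MIN_DAYS:
        raise ValueError(f"need >= {MIN_DAYS} usable days, got {len(sub)}")
    cset = CandidateSet(
        response=f"{resource}_use",
        models=models if models is not None else SELECTION_MODELS[resource],
        random_intercept=random_intercept,
    )
    averaged = fit_candidate_set(sub, cset)
    from .formula import base_columns

    cols: set[str] = set()
    for m in cset.models:
        for t in m:
            cols.update(base_columns(t))
    return SelectionModelSet(species, resource, averaged, _train_range(sub, cols))


def fit_abundance(
    records: pd.DataFrame,
    species: str,
    response: str,
    models: list[tuple[str, ...]] | None = None,
    random_intercept: str | None = "month",
) -> AbundanceModelSet:
    """Fit and average the stage-2 daily abundance candidates.

    The count response is transformed per the species rule before fitting;
    days without an occupied available cell are excluded (use means are
    undefined there).
    """
    if response not in {"flock", "individual"}:
        raise ValueError("response must be 'flock' or 'individual'")
    sub = _species_days(records, species)
    if len(sub) < MIN_DAYS:
        raise ValueError(f"need >= {MIN_DAYS} usable days, got {len(sub)}")
    tag = abundance_transform(species, response)
    col = f"{response}_count"
    sub = sub.copy()
    sub["_response"] = transform(sub[col].to_numpy(float), tag)
    cset = CandidateSet(
        response="_response",
        models=models if models is not None else ABUNDANCE_MODELS,
        random_intercept=random_intercept,
    )
    averaged = fit_candidate_set(sub, cset)
    from .formula import base_columns

    cols: set[str] = set()
    for m in cset.models:
        for t in m:
            cols.update(base_columns(t))
    return AbundanceModelSet(species, response, tag, averaged, _train_range(sub, cols))


def predict_daily(
    selection_sets: dict[str, SelectionModelSet],
    abundance_sets: dict[str, AbundanceModelSet],
    new_records: pd.DataFrame,
) -> pd.DataFrame:
    """Chain the fitted stages over new availability rows.

    Stage 1 predicts use from availability; stage 2 consumes predicted use,
    availability SDs and the reversal fraction. The month random effect is
    set to its population mean (zero) for new data, predictions are
    back-transformed to the count scale, and a flag marks rows where any
    predictor leaves its training range.
    """
    for r in RESOURCES:
        if r not in selection_sets:
            raise ValueError(f"missing fitted selection set for {r!r}")
    for resp in ("flock", "individual"):
        if resp not in abundance_sets:
            raise ValueError(f"missing fitted abundance set for {resp!r}")
    work = new_records.copy()
    extrap = np.zeros(len(work), dtype=bool)
    for r in RESOURCES:
        sset = selection_sets[r]
        for col, row in sset.training_range.iterrows():
            if col in work.columns and col not in (f"{x}_use" for x in RESOURCES):
                v = work[col].to_numpy(float)
                extrap |= (v < row["min"]) | (v > row["max"])
        work[f"{r}_use"] = sset.averaged.predict(work, include_random=False)
    out = {
        "date": work["date"].to_numpy() if "date" in work else np.arange(len(work)),
        "species": work["species"] if "species" in work else "",
    }
    for r in RESOURCES:
        out[f"{r}_use_pred"] = work[f"{r}_use"]
    use_cols = {f"{x}_use" for x in RESOURCES}
    for resp in ("flock", "individual"):
        aset = abundance_sets[resp]
        for col, row in aset.training_range.iterrows():
            if col in work.columns and col not in use_cols:
                v = work[col].to_numpy(float)
                extrap |= (v < row["min"]) | (v > row["max"])
        eta = aset.averaged.predict(work, include_random=False)
        if aset.transform_tag == "fourth_root":
            eta = np.maximum(eta, 0.0)
        else:  # inverse transforms blow up near zero; clip to the transformed range
            eta = np.maximum(eta, 1e-6)
        out[resp] = inverse_transform(eta, aset.transform_tag)
    out["extrapolated"] = extrap
    return pd.DataFrame(out)


def flock_individual_r2(records: pd.DataFrame, species: str | None = None) -> tuple[pd.Series, float]:
    """Per-year squared correlation of daily flock vs individual counts.

    Returns (per-year R^2 series, mean). Years with fewer than 10 days or a
    constant series get NaN.
    """
    sub = records if species is None else records[records["species"] == species]
    years = pd.to_datetime(sub["date"]).dt.year
    out = {}
    for year, grp in sub.groupby(years):
        f = grp["flock_count"].to_numpy(float)
        i = grp["individual_count"].to_numpy(float)
        if len(grp) < 10 or np.std(f) == 0 or np.std(i) == 0:
            out[year] = np.nan
            continue
        out[year] = float(np.corrcoef(f, i)[0, 1] ** 2)
    series = pd.Series(out, name="r2")
    return series, float(series.mean())
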