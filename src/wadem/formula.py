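"""Tiny term grammar shared by the model-selection and mixed-model layers.

Terms are strings over base column names: a main effect ``"depth"``, a square
``"depth^2"``, or a product interaction ``"depth*recess"``. Columns are used
on their raw scale, as is conventional for these covariates (cm, cm/day,
days).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def base_columns(term: str) -> list[str]:
    """Base columns a term references (e.g. ``"a*b" -> ["a", "b"]``)."""
    if term.endswith("^2"):
        return [term[:-2]]
    if "*" in term:
        return term.split("*")
    return [term]


def term_values(table: pd.DataFrame, term: str) -> np.ndarray:
    if term.endswith("^2"):
        return table[term[:-2]].to_numpy(float) ** 2
    if "*" in term:
        a, b = term.split("*")
        return table[a].to_numpy(float) * table[b].to_numpy(float)
    return table[term].to_numpy(float)


def design_matrix(table: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix for a term list."""
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for t in terms:
        cols.append(term_values(table, t))
        names.append(t)
    return np.column_stack(cols), names
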