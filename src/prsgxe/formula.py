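"""A small model-formula grammar and design-matrix builder.

The grammar mirrors the statsmodels/R inline-formula convention used for every
model in this package::

    BMI ~ 1 + PRS + age + C(sex) + C(activity) + PRS:C(activity)
    resid ~ 0 + PRS + C(activity) + C(activity):I(PRS > 0.783)

* ``1`` / ``0`` — include / suppress the intercept (implicit intercept when
  neither is written).
* ``name`` — numeric covariate, taken from the data column of that name.
* ``C(name)`` — categorical factor with treatment (reference-level) coding.
  The reference is the first category of an ordered categorical column, an
  entry of the ``references`` mapping, or the first sorted level.
* ``I(name op value)`` — binary indicator on a numeric column,
  ``op`` one of ``>  >=  <  <=``.
* ``a:b`` — product of two factors.

Coding rules (fixed, documented):

* with an intercept, every categorical factor — alone or inside a product —
  is reduced to its non-reference levels (treatment coding);
* without an intercept, the first categorical main effect and any categorical
  appearing inside a product use full (one column per level) coding, so the
  no-intercept threshold-search model spans one column per
  activity-level x group cell.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDesignError, InvalidInputError

_CAT_RE = re.compile(r"^C\(\s*([A-Za-z_]\w*)\s*\)$")
_IND_RE = re.compile(
    r"^I\(\s*([A-Za-z_]\w*)\s*(>=|<=|>|<)\s*([-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?)\s*\)$"
)
_NUM_RE = re.compile(r"^[A-Za-z_]\w*$")

_OPS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


@dataclass(frozen=True)
class Factor:
    """One multiplicand of a model term."""

    kind: str  # "num" | "cat" | "ind"
    name: str
    op: str | None = None
    value: float | None = None

    def label(self) -> str:
        if self.kind == "num":
            return self.name
        if self.kind == "cat":
            return f"C({self.name})"
        return f"I({self.name} {self.op} {self.value:g})"


@dataclass(frozen=True)
class ModelSpec:
    """Parsed formula: response, intercept flag, and product terms."""

    response: str
    intercept: bool
    terms: tuple[tuple[Factor, ...], ...]
    formula: str = ""

    @property
    def variables(self) -> set[str]:
        names = {self.response}
        for term in self.terms:
            names.update(f.name for f in term)
        return names


def _parse_factor(text: str) -> Factor:
    text = text.strip()
    m = _CAT_RE.match(text)
    if m:
        return Factor("cat", m.group(1))
    m = _IND_RE.match(text)
    if m:
        return Factor("ind", m.group(1), m.group(2), float(m.group(3)))
    if _NUM_RE.match(text):
        return Factor("num", text)
    raise InvalidInputError(f"cannot parse model term {text!r}")


def parse_formula(formula: str) -> ModelSpec:
    """Parse ``response ~ term + term + ...`` into a :class:`ModelSpec`."""
    if "~" not in formula:
        raise InvalidInputError(f"formula {formula!r} lacks '~'")
    lhs, rhs = formula.split("~", 1)
    response = lhs.strip()
    if not _NUM_RE.match(response):
        raise InvalidInputError(f"invalid response name {response!r}")
    intercept: bool | None = None
    terms: list[tuple[Factor, ...]] = []
    # '+' never occurs inside C()/I() except as part of a numeric literal's
    # exponent, which the literal regex consumes before we split.  Guard by
    # splitting only on '+' outside parentheses.
    depth, start, pieces = 0, 0, []
    for i, ch in enumerate(rhs):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "+" and depth == 0:
            pieces.append(rhs[start:i])
            start = i + 1
    pieces.append(rhs[start:])
    for piece in pieces:
        piece = piece.strip()
        if not piece:
            raise InvalidInputError(f"empty term in formula {formula!r}")
        if piece == "1":
            intercept = True
            continue
        if piece == "0":
            intercept = False
            continue
        factors = tuple(_parse_factor(p) for p in _split_interaction(piece))
        if len(factors) > 2:
            raise InvalidInputError(f"only two-way products supported: {piece!r}")
        terms.append(factors)
    if intercept is None:
        intercept = True
    return ModelSpec(response, intercept, tuple(terms), formula=formula.strip())


def _split_interaction(piece: str) -> list[str]:
    depth, start, out = 0, 0, []
    for i, ch in enumerate(piece):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == ":" and depth == 0:
            out.append(piece[start:i])
            start = i + 1
    out.append(piece[start:])
    return out


def _observed_levels(series: pd.Series, name: str, references: Mapping[str, str]) -> list[str]:
    if isinstance(series.dtype, pd.CategoricalDtype):
        levels = [lv for lv in series.cat.categories if (series == lv).any()]
    else:
        levels = sorted(series.dropna().unique().tolist())
    if len(levels) < 2:
        raise DegenerateDesignError(
            f"categorical factor '{name}' has fewer than 2 observed levels"
        )
    ref = references.get(name)
    if ref is not None:
        if ref not in levels:
            raise InvalidInputError(f"reference level {ref!r} not observed in '{name}'")
        levels = [ref] + [lv for lv in levels if lv != ref]
    return levels


def _factor_columns(
    factor: Factor,
    data: pd.DataFrame,
    reduced: bool,
    references: Mapping[str, str],
) -> list[tuple[str, np.ndarray]]:
    if factor.kind == "num":
        return [(factor.name, data[factor.name].to_numpy(dtype=float))]
    if factor.kind == "ind":
        vals = _OPS[factor.op](data[factor.name].to_numpy(dtype=float), factor.value)
        return [(factor.label(), vals.astype(float))]
    levels = _observed_levels(data[factor.name], factor.name, references)
    chosen = levels[1:] if reduced else levels
    tag = "T." if reduced else ""
    col = data[factor.name]
    return [
        (f"C({factor.name})[{tag}{lv}]", (col == lv).to_numpy(dtype=float))
        for lv in chosen
    ]


def build_design(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    references: Mapping[str, str] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Build the response series and design matrix for ``spec``.

    Rows with a missing value in any referenced variable are dropped
    (listwise deletion); the returned objects share the surviving index.
    """
    if isinstance(spec, str):
        spec = parse_formula(spec)
    references = references or {}
    missing_cols = spec.variables - set(data.columns)
    if missing_cols:
        raise InvalidInputError(f"variables absent from data: {sorted(missing_cols)}")
    used = data.loc[:, sorted(spec.variables)]
    mask = used.notna().all(axis=1)
    d = data.loc[mask]
    if d.empty:
        raise InvalidInputError("no complete cases for the requested model")

    columns: list[tuple[str, np.ndarray]] = []
    if spec.intercept:
        columns.append(("Intercept", np.ones(len(d))))
    saw_cat_main = False
    for term in spec.terms:
        has_cat = any(f.kind == "cat" for f in term)
        if spec.intercept:
            reduced = True
        elif len(term) == 1 and has_cat:
            reduced = saw_cat_main  # first categorical main effect gets full coding
            saw_cat_main = True
        else:
            reduced = not has_cat  # categoricals inside products: full coding
        parts: Sequence[list[tuple[str, np.ndarray]]] = [
            _factor_columns(f, d, reduced, references) for f in term
        ]
        if len(parts) == 1:
            columns.extend(parts[0])
        else:
            for name_a, col_a in parts[0]:
                for name_b, col_b in parts[1]:
                    columns.append((f"{name_a}:{name_b}", col_a * col_b))

    seen = set()
    names, arrays = [], []
    for name, arr in columns:
        if name in seen:
            raise InvalidInputError(f"duplicate design column {name!r}")
        seen.add(name)
        names.append(name)
        arrays.append(arr)
    X = pd.DataFrame(np.column_stack(arrays), index=d.index, columns=names)
    return d[spec.response], X
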