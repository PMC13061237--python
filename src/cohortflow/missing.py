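"""Missing-value standardization.

Clinical exports encode missingness in many ways ("", "NA", "None", a
bare "."). This module rewrites all of them, plus native nulls, to a
single internal marker (NaN) so that downstream summaries can treat
missingness uniformly — and visibly, as its own category.

No imputation is performed anywhere in the package; missingness is
preserved and displayed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .model import MISSING_LABEL_DEFAULT, VariableSpec

#: Default string representations treated as missing, beyond native nulls.
#: User-overridable; numeric sentinel codes (e.g. -999) are deliberately
#: NOT included — silently coercing numbers is dangerous, so users must
#: opt in by adding them to the token set.
DEFAULT_MISSING_TOKENS = frozenset(
    {"", "NA", "N/A", "None", "NULL", "NaN", "nan", "."}
)


@dataclass(frozen=True)
class MissingPolicy:
    """Which string tokens count as missing, and the display label.

    Tokens are matched after trimming surrounding whitespace; alphabetic
    tokens match case-insensitively ("None", "none" and "NONE" are all
    missing under the default set).
    """

    tokens: frozenset[str] = DEFAULT_MISSING_TOKENS
    missing_label: str = MISSING_LABEL_DEFAULT

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", frozenset(self.tokens))

    def _matchers(self) -> tuple[set[str], set[str]]:
        """(exact tokens, casefolded alphabetic tokens)."""
        exact, folded = set(), set()
        for tok in self.tokens:
            t = tok.strip()
            if any(ch.isalpha() for ch in t):
                folded.add(t.casefold())
            else:
                exact.add(t)
        return exact, folded

    def is_missing_token(self, value: object) -> bool:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return True
        if not isinstance(value, str):
            return False
        exact, folded = self._matchers()
        s = value.strip()
        return s in exact or s.casefold() in folded


def standardize_missing(
    table: pd.DataFrame, policy: MissingPolicy | None = None
) -> pd.DataFrame:
    """Return a copy of ``table`` with all missing representations as NaN.

    Pure normalization: row and column counts are unchanged, non-missing
    cells are untouched, and the operation is idempotent.
    """
    policy = policy or MissingPolicy()
    exact, folded = policy._matchers()
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_object_dtype(out[col]) or isinstance(
            out[col].dtype, pd.CategoricalDtype
        ) or pd.api.types.is_string_dtype(out[col]):
            series = out[col]
            if isinstance(series.dtype, pd.CategoricalDtype):
                series = series.astype(object)
            mask = series.map(
                lambda v: isinstance(v, str)
                and (v.strip() in exact or v.strip().casefold() in folded)
            )
            if mask.any():
                series = series.where(~mask, np.nan)
            out[col] = series
    return out


def missingness_profile(
    table: pd.DataFrame, specs: list[VariableSpec]
) -> dict[str, float]:
    """Fraction of missing cells per tracked variable, each in [0, 1]."""
    missing = [s.name for s in specs if s.name not in table.columns]
    if missing:
        raise SchemaError(f"columns not found in table: {missing}")
    n = len(table)
    return {
        s.name: (float(table[s.name].isna().sum()) / n) if n else 0.0
        for s in specs
    }
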