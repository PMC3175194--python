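"""Treatment coding of categorical predictors into design-matrix dummies.

Column order is deterministic: covariates in the order of the supplied
reference-level mapping, non-reference levels in their declared categorical
order.  Dummy columns are named ``{covariate}_{level}`` with characters
unsafe for file/column names replaced by underscores.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_REFERENCE_LEVELS", "code_predictors", "term_name"]

#: Reference levels mirroring the usual presentation for this kind of study:
#: female, 65+, low expected-resource-use band, few ambulatory diagnostic
#: groups, high income/education, best self-rated health, no regular doctor,
#: no chronic condition, urban residence.
DEFAULT_REFERENCE_LEVELS = {
    "gender": "female",
    "age": "65_79",
    "rub": "0_1",
    "adg": "0_5",
    "income": "high",
    "education": "high",
    "srh": "excellent_vg",
    "doctor": "no",
    "chronic": "none",
    "residence": "urban",
}


def term_name(covariate: str, level: str) -> str:
    safe = re.sub(r"[^0-9A-Za-z]+", "_", str(level)).strip("_")
    return f"{covariate}_{safe}"


def code_predictors(cohort: pd.DataFrame, reference_levels: dict[str, str]):
    """Return ``(design, term_map)``: 0/1 dummy columns for every
    non-reference level, and a map ``term -> (covariate, level)``.

    Raises ``KeyError`` for a missing covariate, ``ValueError`` if the
    reference level is absent from the declared levels or an unseen value
    appears in the data.  Columns that are identically zero (all rows at the
    reference) are kept but flagged with a warning, since they make the
    design rank-deficient.
    """
    columns: dict[str, np.ndarray] = {}
    term_map: dict[str, tuple[str, str]] = {}
    for cov, ref in reference_levels.items():
        if cov not in cohort.columns:
            raise KeyError(f"covariate {cov!r} not present in cohort")
        col = cohort[cov]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(col.cat.categories)
        else:
            levels = sorted(map(str, pd.unique(col.astype(str))))
        values = col.astype(str).to_numpy()
        if ref not in levels:
            raise ValueError(
                f"reference level {ref!r} not among levels {levels} of {cov!r}"
            )
        unseen = set(values) - set(map(str, levels))
        if unseen:
            raise ValueError(f"unseen level(s) {sorted(unseen)} in covariate {cov!r}")
        for lv in levels:
            if str(lv) == str(ref):
                continue
            name = term_name(cov, lv)
            dummy = (values == str(lv)).astype(float)
            if dummy.sum() == 0:
                warnings.warn(
                    f"dummy {name!r} is identically zero (collinearity risk)",
                    stacklevel=2,
                )
            columns[name] = dummy
            term_map[name] = (cov, str(lv))
    design = pd.DataFrame(columns, index=cohort.index)
    return design, term_map
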