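"""Group comparisons and nearest-neighbor feature-selection analyses.

Per-parameter omnibus Kruskal-Wallis tests across the three groups with
Wilcoxon rank-sum post-hocs gated at p < 0.05 (no multiplicity correction),
and RReliefF rankings of the predictors of the coordination parameters that
separate patients from controls (DST CV, GA, phase deviation, PCI), run
separately per group with clinical covariates added for patients only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinematics import KINEMATIC_COLUMNS
from .kinetics import KINETIC_COLUMNS
from .relieff import relieff_rank

__all__ = [
    "GroupComparisonRow",
    "FeatureRanking",
    "compare_groups",
    "run_table4_analyses",
    "DEMOGRAPHIC_PREDICTORS",
    "CLINICAL_PREDICTORS",
    "TABLE4_RESPONSES",
]

ALPHA = 0.05

DEMOGRAPHIC_PREDICTORS = ["age_years", "sex", "weight_kg", "height_m"]
CLINICAL_PREDICTORS = [
    "updrs_iii",
    "mmse",
    "ledd_mg",
    "disease_duration_years",
    "affected_side",
]
TABLE4_RESPONSES = ("DST CV", "GA", "phi deviation", "PCI")

# a response's algebraic components are never offered as its predictors
_RESPONSE_EXCLUSIONS: Dict[str, List[str]] = {
    "DST CV": ["DST CV"],
    "GA": ["GA"],
    "phi deviation": ["phi deviation", "phi deviation [deg]", "PCI"],
    "PCI": ["PCI", "phi CV", "phi deviation", "phi deviation [deg]"],
}


@dataclass
class GroupComparisonRow:
    parameter: str
    medians: Dict[str, float]
    sds: Dict[str, float]
    chi_square_kw: Optional[float] = None
    p_value: Optional[float] = None
    posthoc_p: Dict[str, float] = field(default_factory=dict)
    flag: Optional[str] = None

    def to_row(self) -> dict:
        row = {"parameter": self.parameter}
        for g, m in self.medians.items():
            row[f"{g} median"] = m
            row[f"{g} sd"] = self.sds[g]
        row["chi2_KW"] = self.chi_square_kw
        row["p"] = self.p_value
        for pair, p in self.posthoc_p.items():
            row[f"p {pair}"] = p
        row["flag"] = self.flag
        return row


@dataclass
class FeatureRanking:
    response: str
    group: str
    ranking: List[tuple]  # (predictor, weight, informative)

    def to_rows(self) -> List[dict]:
        return [
            {
                "response": self.response,
                "group": self.group,
                "rank": r + 1,
                "predictor": name,
                "weight": w,
                "informative": info,
            }
            for r, (name, w, info) in enumerate(self.ranking)
        ]


def compare_groups(
    feature_table: pd.DataFrame,
    group_col: str = "group",
    parameters: Optional[Sequence[str]] = None,
) -> List[GroupComparisonRow]:
    """Kruskal-Wallis omnibus per parameter, rank-sum post-hocs when p < 0.05.

    Post-hoc pairs are each group vs YC plus PD vs AMC, mirroring the
    reporting convention of the group tables.  Parameters constant across all
    subjects are flagged and left untested.
    """
    groups = list(dict.fromkeys(feature_table[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = feature_table[group_col].value_counts()
    if sizes.min() < 3:
        raise ValueError("need at least 3 subjects per group")
    if parameters is None:
        parameters = [
            c
            for c in feature_table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(feature_table[c])
        ]
    rows = []
    for param in parameters:
        per_group = {g: feature_table.loc[feature_table[group_col] == g, param].to_numpy()
                     for g in groups}
        medians = {g: float(np.median(v)) for g, v in per_group.items()}
        sds = {g: float(np.std(v, ddof=1)) for g, v in per_group.items()}
        values = np.concatenate(list(per_group.values()))
        if np.all(values == values[0]):
            rows.append(
                GroupComparisonRow(param, medians, sds, flag="constant across subjects")
            )
            continue
        h, p = sps.kruskal(*per_group.values())
        row = GroupComparisonRow(param, medians, sds, float(h), float(p))
        if p < ALPHA:
            pairs = []
            for g in groups:
                if g != "YC" and "YC" in per_group:
                    pairs.append((g, "YC"))
            if "PD" in per_group and "AMC" in per_group:
                pairs.append(("PD", "AMC"))
            for a, b in pairs:
                _, pp = sps.ranksums(per_group[a], per_group[b])
                row.posthoc_p[f"{a} vs {b}"] = float(pp)
        rows.append(row)
    return rows


def _encode(col: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(float)
    # binary categorical (sex, affected side) -> 0/1 in sorted label order
    labels = sorted(col.dropna().unique())
    return col.map({lab: float(i) for i, lab in enumerate(labels)}).to_numpy(float)


def run_table4_analyses(
    feature_table: pd.DataFrame,
    responses: Sequence[str] = TABLE4_RESPONSES,
    k: int = 10,
    group_col: str = "group",
) -> List[FeatureRanking]:
    """Per-group RReliefF rankings for each coordination response.

    The predictor pool is demographics + kinematics + kinetics, minus the
    response and its algebraic components; for the PD group the clinical
    covariates join the pool.  Returns one ranking per (response, group).
    """
    base_pool = DEMOGRAPHIC_PREDICTORS + KINEMATIC_COLUMNS + KINETIC_COLUMNS
    out: List[FeatureRanking] = []
    for response in responses:
        if response not in feature_table.columns:
            raise ValueError(f"response {response!r} not in feature table")
        excluded = set(_RESPONSE_EXCLUSIONS.get(response, [response]))
        for group in dict.fromkeys(feature_table[group_col]):
            sub = feature_table[feature_table[group_col] == group]
            pool = [c for c in base_pool if c in sub.columns and c not in excluded]
            if group == "PD":
                pool += [c for c in CLINICAL_PREDICTORS if c in sub.columns]
            X = np.column_stack([_encode(sub[c]) for c in pool])
            y = sub[response].to_numpy(float)
            ranking = relieff_rank(X, y, k=k, mode="regression", feature_names=pool)
            out.append(FeatureRanking(response=response, group=str(group), ranking=ranking))
    return out
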