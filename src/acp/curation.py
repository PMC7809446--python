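"""Candidate selection: correlation threshold, annotation filters, Venn counts.

Proteins whose mean profile correlation meets the threshold (R >= 0.9 by
default) are intersected with annotation-derived sets — essential genes,
polytopic membrane proteins (>= 3 predicted TM spans) and a subcellular
localization (ER) — to yield the final candidate list. Every exclusion
carries a machine-readable reason, and the three-way Venn region counts
are reported for bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterRules",
    "CurationResult",
    "select_correlated",
    "apply_filters",
    "near_threshold_report",
    "venn3_counts",
]

ANNOTATION_COLUMNS = ["protein_id", "essential", "tm_spans", "localization"]


@dataclass(frozen=True)
class FilterRules:
    """Curation rules: threshold and annotation requirements.

    ``inclusive`` selects R >= threshold (the default) rather than
    R > threshold. Setting ``require_essential=False``, ``min_tm=0`` and
    ``localization=None`` turns the corresponding filter off.
    """

    r_threshold: float = 0.9
    inclusive: bool = True
    require_essential: bool = True
    min_tm: int = 3
    localization: str | None = "ER"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r_threshold <= 1.0:
            raise ValueError("r_threshold must be in [-1, 1]")
        if self.min_tm < 0:
            raise ValueError("min_tm must be >= 0")


@dataclass
class CurationResult:
    """Outcome of the filter pipeline.

    ``venn_counts`` holds the region sizes of the three-way diagram over
    A = correlated, B = essential (annotated), C = membrane (tm >= min_tm),
    keyed "A", "B", "C", "AB", "AC", "BC", "ABC" (intersection sizes, not
    exclusive regions). ``excluded`` lists (protein_id, reason) for every
    correlated protein that did not reach the final list.
    """

    correlated_set: set[str]
    essential_overlap: set[str]
    membrane_overlap: set[str]
    final_candidates: set[str]
    venn_counts: dict[str, int]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    rules: FilterRules = field(default_factory=FilterRules)

    def to_dict(self) -> dict:
        return {
            "rules": {
                "r_threshold": self.rules.r_threshold,
                "inclusive": self.rules.inclusive,
                "require_essential": self.rules.require_essential,
                "min_tm": self.rules.min_tm,
                "localization": self.rules.localization,
            },
            "correlated_set": sorted(self.correlated_set),
            "essential_overlap": sorted(self.essential_overlap),
            "membrane_overlap": sorted(self.membrane_overlap),
            "final_candidates": sorted(self.final_candidates),
            "venn_counts": dict(self.venn_counts),
            "excluded": [list(t) for t in sorted(self.excluded)],
        }

    def summary(self) -> str:
        v = self.venn_counts
        lines = [
            f"correlated (R threshold {self.rules.r_threshold}, "
            f"{'inclusive' if self.rules.inclusive else 'strict'}): {v['A']}",
            f"  ∩ essential: {v['AB']}",
            f"  ∩ membrane (TM >= {self.rules.min_tm}): {v['AC']}",
            f"  ∩ essential ∩ membrane: {v['ABC']}",
            f"final candidates"
            + (f" ({self.rules.localization}-localized)" if self.rules.localization else "")
            + f": {len(self.final_candidates)}",
        ]
        if self.final_candidates:
            lines.append("  " + ", ".join(sorted(self.final_candidates)))
        return "\n".join(lines)


def select_correlated(
    records: pd.DataFrame | pd.Series,
    threshold: float = 0.9,
    inclusive: bool = True,
) -> set[str]:
    """Protein ids whose mean correlation meets the threshold.

    ``records`` is either the aggregated correlation table (with an
    ``r_mean`` column) or a Series of per-protein mean correlations.
    Undefined (NaN) correlations never pass.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [-1, 1]")
    r = records["r_mean"] if isinstance(records, pd.DataFrame) else records
    mask = r >= threshold if inclusive else r > threshold
    mask &= r.notna()
    return set(r.index[mask])


def _localizations(value) -> set[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    return {tok.strip() for tok in str(value).split(";") if tok.strip()}


def _check_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    if annotations["protein_id"].duplicated().any():
        dup = annotations["protein_id"][annotations["protein_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate protein_id in annotations: {dup!r}")
    ann = annotations.set_index("protein_id")
    ann["essential"] = ann["essential"].astype(bool)
    ann["tm_spans"] = ann["tm_spans"].astype(int)
    if (ann["tm_spans"] < 0).any():
        raise ValueError("tm_spans must be >= 0")
    return ann


def apply_filters(
    correlated: set[str],
    annotations: pd.DataFrame,
    rules: FilterRules = FilterRules(),
) -> CurationResult:
    """Intersect the correlated set with the annotation-derived filters.

    Unannotated proteins are conservatively excluded (reason
    "unannotated"); multi-localized proteins (semicolon-separated labels)
    pass the localization rule if any label matches. The filter pipeline
    is pure set intersection, hence order-independent.
    """
    ann = _check_annotations(annotations)
    essential_all = set(ann.index[ann["essential"]])
    membrane_all = set(ann.index[ann["tm_spans"] >= rules.min_tm])

    excluded: list[tuple[str, str]] = []
    final: set[str] = set()
    for pid in sorted(correlated):
        if pid not in ann.index:
            excluded.append((pid, "unannotated"))
            continue
        reasons = []
        if rules.require_essential and not bool(ann.at[pid, "essential"]):
            reasons.append("not-essential")
        if int(ann.at[pid, "tm_spans"]) < rules.min_tm:
            reasons.append(f"tm_spans<{rules.min_tm}")
        if rules.localization is not None and rules.localization not in _localizations(
            ann.at[pid, "localization"]
        ):
            reasons.append(f"not-{rules.localization}")
        if reasons:
            excluded.append((pid, ";".join(reasons)))
        else:
            final.add(pid)

    return CurationResult(
        correlated_set=set(correlated),
        essential_overlap=correlated & essential_all,
        membrane_overlap=correlated & membrane_all,
        final_candidates=final,
        venn_counts=venn3_counts(correlated, essential_all, membrane_all),
        excluded=excluded,
        rules=rules,
    )


def venn3_counts(A: set, B: set, C: set) -> dict[str, int]:
    """Intersection sizes for a three-set Venn diagram.

    Keys are "A", "B", "C" (set sizes) and "AB", "AC", "BC", "ABC"
    (pairwise and triple intersection sizes). These satisfy the
    inclusion-exclusion identity |A ∪ B ∪ C| = |A|+|B|+|C|-|AB|-|AC|-|BC|+|ABC|.
    """
    return {
        "A": len(A),
        "B": len(B),
        "C": len(C),
        "AB": len(A & B),
        "AC": len(A & C),
        "BC": len(B & C),
        "ABC": len(A & B & C),
        "union": len(A | B | C),
    }


def near_threshold_report(
    records: pd.DataFrame | pd.Series,
    threshold: float = 0.9,
    margin: float = 0.02,
) -> pd.DataFrame:
    """Proteins just missing the cut: threshold - margin <= r_mean < threshold.

    Makes the manual rescue of borderline candidates (a protein at
    R = 0.89 against a 0.9 cut-off) reproducible. Proteins already
    passing are not listed; margin 0 yields an empty report.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if isinstance(records, pd.Series):
        records = records.to_frame("r_mean")
    r = records["r_mean"]
    mask = (r >= threshold - margin) & (r < threshold) & r.notna()
    out = records.loc[mask].sort_values("r_mean", ascending=False)
    out.index.name = "protein_id"
    return out
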