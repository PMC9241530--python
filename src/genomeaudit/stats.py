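"""Comparative equivalence statistics and report tables.

Covers the headline audit quantities: N50-ratio equivalence calls
(an assembly is equivalent-or-superior when its N50 is at least 95% of the
counterpart's), signed GC deltas in percentage points, extreme-outlier
detection by the median + 3*IQR fence, category enrichment folds, and the
three joined report tables (assembly equivalence, whole-genome alignment,
variant effects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .compare import ComparisonSummary
from .effects import EffectTally
from .metrics import AssemblyMetrics

__all__ = [
    "PairwiseMetricsRow",
    "OutlierResult",
    "EnrichmentResult",
    "n50_equivalence",
    "gc_delta",
    "extreme_outliers",
    "enrichment_fold",
    "build_comparison_tables",
]

N50_EQUIVALENCE_THRESHOLD = 0.95
IQR_FOLD = 3.0


@dataclass(frozen=True)
class PairwiseMetricsRow:
    n50_ratio: float
    log2_n50_ratio: float
    equivalence: str  # equivalent_or_superior | more_fragmented
    threshold: float = N50_EQUIVALENCE_THRESHOLD


@dataclass(frozen=True)
class OutlierResult:
    median: float
    q1: float
    q3: float
    boundary: float
    flagged: Tuple[str, ...]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class EnrichmentResult:
    group_a_mean: float
    group_b_mean: float
    fold: float  # nan when group_b_mean == 0
    n_a: int
    n_b: int

    @property
    def computable(self) -> bool:
        return not math.isnan(self.fold)


def n50_equivalence(
    atcc_n50: int | float,
    public_n50: int | float,
    threshold: float = N50_EQUIVALENCE_THRESHOLD,
) -> PairwiseMetricsRow:
    """Equivalence call for one N50 pair: ratio >= threshold (boundary inclusive)."""
    if atcc_n50 <= 0 or public_n50 <= 0:
        raise ValueError("N50 values must be positive")
    ratio = atcc_n50 / public_n50
    return PairwiseMetricsRow(
        n50_ratio=ratio,
        log2_n50_ratio=math.log2(ratio),
        equivalence=(
            "equivalent_or_superior" if ratio >= threshold else "more_fragmented"
        ),
        threshold=threshold,
    )


def gc_delta(gc_a: float, gc_b: float) -> float:
    """Signed GC difference in percentage points: 100*(gc_a - gc_b)."""
    for v in (gc_a, gc_b):
        if not 0.0 <= v <= 1.0:
            raise ValueError("GC fractions must lie in [0, 1]")
    return 100.0 * (gc_a - gc_b)


def extreme_outliers(values: Mapping[str, float]) -> OutlierResult:
    """Flag ids whose value exceeds median + 3*(Q3 - Q1).

    Quartiles use linear interpolation between order statistics.  With an
    all-equal input the IQR collapses to zero and only values strictly
    above the median are flagged.
    """
    if len(values) < 4:
        raise ValueError("extreme-outlier detection needs at least 4 values")
    arr = np.asarray(list(values.values()), dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    boundary = med + IQR_FOLD * (q3 - q1)
    flagged = tuple(k for k, v in values.items() if v > boundary)
    return OutlierResult(
        median=float(med), q1=float(q1), q3=float(q3),
        boundary=float(boundary), flagged=flagged,
    )


def enrichment_fold(
    group_a: Sequence[float],
    group_b: Sequence[float],
    estimator: str = "mean",
) -> EnrichmentResult:
    """Fold difference between two groups' per-assembly counts.

    ``fold = estimator(group_a) / estimator(group_b)``; reported as NaN
    (not computable) when the denominator is zero.
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("both groups must be non-empty")
    if estimator == "mean":
        a, b = float(np.mean(group_a)), float(np.mean(group_b))
    elif estimator == "median":
        a, b = float(np.median(group_a)), float(np.median(group_b))
    else:
        raise ValueError("estimator must be 'mean' or 'median'")
    fold = a / b if b != 0 else float("nan")
    return EnrichmentResult(a, b, fold, len(group_a), len(group_b))


Key = Tuple[str, str]  # (strain_key, ref_accession)


def _check_keys(name_sets: Dict[str, Iterable[Key]]) -> List[Key]:
    sets = {name: set(keys) for name, keys in name_sets.items()}
    union = set().union(*sets.values())
    orphans = {
        name: sorted(union - s) for name, s in sets.items() if union - s
    }
    if orphans:
        details = "; ".join(
            f"{name} missing {missing}" for name, missing in orphans.items()
        )
        raise KeyError(f"comparison inputs do not join: {details}")
    return sorted(union)


def build_comparison_tables(
    metrics_pairs: Mapping[Key, Tuple[AssemblyMetrics, AssemblyMetrics]],
    summaries: Mapping[Key, ComparisonSummary],
    effects: Mapping[Key, EffectTally],
    threshold: float = N50_EQUIVALENCE_THRESHOLD,
) -> Dict[str, pd.DataFrame]:
    """Emit the three report tables, one row per (strain, public accession).

    ``metrics_pairs`` maps each key to (reference-material assembly
    metrics, public assembly metrics).  Log ratios are base 2, reference
    over public, so swapping a pair negates the value.  Raises ``KeyError``
    listing orphans when the three inputs do not share the same keys.
    """
    keys = _check_keys(
        {"metrics": metrics_pairs.keys(), "summaries": summaries.keys(),
         "effects": effects.keys()}
    )
    equiv_rows, align_rows, effect_rows = [], [], []
    for key in keys:
        strain_key, accession = key
        ours, public = metrics_pairs[key]
        row = n50_equivalence(ours.n50, public.n50, threshold)
        equiv_rows.append(
            {
                "strain_key": strain_key,
                "ref_accession": accession,
                "N50_ATCC": ours.n50,
                "N50_RefSeq": public.n50,
                "N50_ratio": row.n50_ratio,
                "log2_N50_ratio": row.log2_n50_ratio,
                "log2_scaffold_ratio": math.log2(
                    ours.contig_count / public.contig_count
                ),
                "log2_length_ratio": math.log2(
                    ours.total_length / public.total_length
                ),
                "GC_ATCC": ours.gc_fraction,
                "GC_RefSeq": public.gc_fraction,
                "GC_delta_points": gc_delta(ours.gc_fraction, public.gc_fraction),
                "equivalence": row.equivalence,
            }
        )
        s = summaries[key]
        align_rows.append(
            {"strain_key": strain_key, "ref_accession": accession, **s.to_row()}
        )
        t = effects[key]
        effect_rows.append(
            {
                "strain_key": strain_key,
                "ref_accession": accession,
                "SNPs": s.snp_count,
                "Indels": s.indel_count,
                "TotalVariants": t.n_variants,
                "TotalSynonymous": t.synonymous,
                "TotalNonsynonymous": t.nonsynonymous,
                "TotalOther": t.other,
                "DuplicateVariants": t.n_duplicate_records,
            }
        )
    return {
        "equivalence": pd.DataFrame(equiv_rows),
        "alignment": pd.DataFrame(align_rows),
        "variants": pd.DataFrame(effect_rows),
    }
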