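"""Observed−expected range analysis over experiment results.

For a focal outcome (e.g. thriving societies with declining religiosity)
nested inside a reference set (all thriving societies), each parameter's
sampled range is cut into equal-width bins; the focal and reference
percentages falling in each bin are compared.  A positive difference marks a
range that over-produces the focal outcome.  The same arithmetic applied to
lower/upper half-ranges of two parameters at once quantifies pairwise
conditions, and a scan over contiguous bin unions proposes narrowed ranges
for a follow-up sampling round — the spectrum-style strategy software
engineers use to localise failing inputs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "observed_expected_by_range",
    "observed_expected_pairwise",
    "propose_range_restrictions",
]


class AnalysisError(ValueError):
    """Raised for unusable focal/reference sets."""


def _check_masks(results: pd.DataFrame, focal_mask, reference_mask):
    focal = np.asarray(focal_mask, dtype=bool)
    reference = np.asarray(reference_mask, dtype=bool)
    if focal.shape[0] != len(results) or reference.shape[0] != len(results):
        raise AnalysisError("masks must match the results table length")
    if not focal.any():
        raise AnalysisError("focal set is empty")
    if (focal & ~reference).any():
        raise AnalysisError("focal set must be a subset of the reference set")
    return focal, reference


def _bin_edges(values: np.ndarray, n_bins: int, declared_range=None) -> np.ndarray:
    if declared_range is not None:
        lo, hi = declared_range
    else:
        lo, hi = float(np.min(values)), float(np.max(values))
    if not lo < hi:
        raise AnalysisError("parameter has zero range")
    return np.linspace(lo, hi, n_bins + 1)


def _bin_counts(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # right-closed bins except the first, matching interval reporting
    idx = np.searchsorted(edges, values, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    return np.bincount(idx, minlength=len(edges) - 1)


def observed_expected_by_range(
    results: pd.DataFrame,
    focal_mask,
    reference_mask,
    parameter: str,
    n_bins: int = 5,
    declared_range: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Per-bin observed/expected percentages and their difference.

    observed = % of focal runs in the bin; expected = % of reference runs in
    the bin; difference = observed − expected, in percentage points.  Bins
    are equal-width over the declared sampling range (or the observed range
    when none is given).
    """
    if n_bins < 2:
        raise AnalysisError("n_bins must be >= 2")
    focal, reference = _check_masks(results, focal_mask, reference_mask)
    values = np.asarray(results[parameter], dtype=float)
    edges = _bin_edges(values[reference], n_bins, declared_range)
    obs = _bin_counts(values[focal], edges) / focal.sum() * 100.0
    exp = _bin_counts(values[reference], edges) / reference.sum() * 100.0
    return pd.DataFrame(
        {
            "parameter": parameter,
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "observed_pct": obs,
            "expected_pct": exp,
            "difference": obs - exp,
        }
    )


def observed_expected_pairwise(
    results: pd.DataFrame,
    focal_mask,
    reference_mask,
    parameter_a: str,
    parameter_b: str,
    declared_range_a: Optional[tuple[float, float]] = None,
    declared_range_b: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Observed−expected differences over the four half-range combinations."""
    focal, reference = _check_masks(results, focal_mask, reference_mask)
    rows = []
    va = np.asarray(results[parameter_a], dtype=float)
    vb = np.asarray(results[parameter_b], dtype=float)
    mid_a = _bin_edges(va[reference], 2, declared_range_a)[1]
    mid_b = _bin_edges(vb[reference], 2, declared_range_b)[1]
    for half_a, mask_a in (("lower", va <= mid_a), ("upper", va > mid_a)):
        for half_b, mask_b in (("lower", vb <= mid_b), ("upper", vb > mid_b)):
            cell = mask_a & mask_b
            obs = (cell & focal).sum() / focal.sum() * 100.0
            exp = (cell & reference).sum() / reference.sum() * 100.0
            rows.append(
                {
                    "parameter_a": parameter_a,
                    "half_a": half_a,
                    "parameter_b": parameter_b,
                    "half_b": half_b,
                    "observed_pct": obs,
                    "expected_pct": exp,
                    "difference": obs - exp,
                }
            )
    return pd.DataFrame(rows)


def propose_range_restrictions(
    results: pd.DataFrame,
    success_column: str,
    parameters: dict[str, tuple[float, float]] | list[str],
    min_effect: float = 10.0,
    n_bins: int = 5,
) -> dict[str, tuple[float, float]]:
    """Propose narrowed (min, max) ranges for a follow-up sampling round.

    For each parameter, finds the smallest contiguous union of bins whose
    summed observed−expected difference exceeds ``min_effect`` percentage
    points (ties broken by the larger difference); parameters with no such
    window yield no proposal.  Focal = rows where ``success_column`` is
    true; reference = all rows.
    """
    focal = np.asarray(results[success_column], dtype=bool)
    reference = np.ones(len(results), dtype=bool)
    if isinstance(parameters, dict):
        items = parameters.items()
    else:
        items = [(p, None) for p in parameters]
    proposals: dict[str, tuple[float, float]] = {}
    for name, declared in items:
        table = observed_expected_by_range(
            results, focal, reference, name, n_bins=n_bins, declared_range=declared
        )
        diff = table["difference"].to_numpy()
        best = None  # (width, -total, lo, hi)
        for i in range(len(diff)):
            total = 0.0
            for j in range(i, len(diff)):
                total += diff[j]
                if total > min_effect:
                    key = (j - i + 1, -total)
                    if best is None or key < best[:2]:
                        best = (
                            j - i + 1,
                            -total,
                            float(table["bin_low"].iloc[i]),
                            float(table["bin_high"].iloc[j]),
                        )
        if best is not None:
            proposals[name] = (best[2], best[3])
    return proposals
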