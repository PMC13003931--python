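"""Supporting assay statistics: ΔCq expression ratios, gel PSI, Sanger
A>I editing, luciferase ratios and the performance-ratio correlation.

All qPCR computations assume perfect amplification efficiency (exact
doubling per cycle), so relative expression is 2^(Cq_control − Cq_target)
with replicate Cq values averaged on the cycle scale before
exponentiation.  Nuclear-to-cytosolic enrichment is the ratio of the
GAPDH-normalized expressions of the two fractions; any per-fraction
dilution shift adds a constant to every Cq in that fraction and cancels
exactly in the ΔCq.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_expression",
    "nuclear_cytosolic_ratio",
    "psi_from_bands",
    "sanger_editing",
    "luciferase_ratio",
    "luciferase_ratios",
    "performance_ratio",
    "pearson_with_p",
]

FRACTIONS = ("nuclear", "cytosolic", "whole")


def _mean_cq(cq: pd.DataFrame, gene: str, sample: str, fraction: str) -> float:
    rows = cq[(cq["gene"] == gene) & (cq["sample_id"] == sample)
              & (cq["fraction"] == fraction)]
    if rows.empty:
        raise KeyError(
            f"no Cq rows for gene={gene!r}, sample={sample!r}, fraction={fraction!r}"
        )
    return float(rows["cq"].mean())


def relative_expression(cq: pd.DataFrame, target_gene: str, control_gene: str,
                        sample: str, fraction: str,
                        average_ratios: bool = False) -> float:
    """Expression of ``target_gene`` relative to ``control_gene``:
    2^(mean Cq_control − mean Cq_target) within (sample, fraction).

    ``average_ratios=True`` instead pairs replicates and averages the
    per-replicate 2^ΔCq ratios (non-default convention).
    """
    if average_ratios:
        t = cq[(cq["gene"] == target_gene) & (cq["sample_id"] == sample)
               & (cq["fraction"] == fraction)].sort_values("replicate")
        c = cq[(cq["gene"] == control_gene) & (cq["sample_id"] == sample)
               & (cq["fraction"] == fraction)].sort_values("replicate")
        if t.empty or c.empty or len(t) != len(c):
            raise KeyError(
                f"unmatched replicate rows for {target_gene!r}/{control_gene!r} "
                f"in sample={sample!r}, fraction={fraction!r}"
            )
        return float(np.mean(2.0 ** (c["cq"].to_numpy() - t["cq"].to_numpy())))
    dcq = _mean_cq(cq, control_gene, sample, fraction) - _mean_cq(
        cq, target_gene, sample, fraction)
    return float(2.0 ** dcq)


def nuclear_cytosolic_ratio(cq: pd.DataFrame, target_gene: str,
                            control_gene: str, sample: str) -> float:
    """Nuclear-to-cytosolic enrichment of the control-normalized expression.

    Invariant to any additive per-fraction Cq shift (dilution factors
    cancel in the control-normalized ΔCq of each fraction).
    """
    nuc = relative_expression(cq, target_gene, control_gene, sample, "nuclear")
    cyt = relative_expression(cq, target_gene, control_gene, sample, "cytosolic")
    return nuc / cyt


def psi_from_bands(lane: pd.DataFrame) -> float:
    """Percent-spliced-in from gel band intensities, adjusted for length.

    Intercalating-dye intensity scales with mass, so the molar amount of a
    band is intensity / length_bp; PSI is the included-isoform molar
    fraction.
    """
    def molar(isoform: str) -> float:
        rows = lane[lane["isoform"] == isoform]
        if rows.empty:
            return 0.0
        intensity = rows["intensity"].to_numpy(dtype=float)
        length = rows["length_bp"].to_numpy(dtype=float)
        if (intensity < 0).any():
            raise ValueError("negative band intensity")
        if (length <= 0).any():
            raise ValueError("non-positive band length")
        return float((intensity / length).sum())

    inc, exc = molar("included"), molar("excluded")
    if inc + exc == 0:
        raise ValueError("both molar amounts are zero; PSI undefined")
    return inc / (inc + exc)


def sanger_editing(a: float, c: float, g: float, t: float) -> float:
    """A>I editing fraction from Sanger peak heights at the edited adenosine.

    Inosine is read as guanosine, so the editing fraction is the G share of
    the A+G signal: g / (a + g).
    """
    if min(a, c, g, t) < 0:
        raise ValueError("peak heights must be non-negative")
    if a + g == 0:
        raise ValueError("a + g = 0: no A/G signal at the edited site")
    return g / (a + g)


def luciferase_ratio(fluc: float, rluc: float) -> float:
    """Firefly/Renilla luminescence ratio for one well."""
    if rluc <= 0:
        raise ValueError("RLuc luminescence must be > 0")
    if fluc < 0:
        raise ValueError("FLuc luminescence must be >= 0")
    return fluc / rluc


def luciferase_ratios(wells: pd.DataFrame) -> pd.DataFrame:
    """Batch form: per-well FLuc/RLuc ratios plus per-condition means.

    ``wells`` columns: condition, fluc, rluc.  Returns the wells with a
    ``ratio`` column and a ``condition_mean`` column broadcast per
    condition.
    """
    out = wells.copy()
    out["ratio"] = [luciferase_ratio(f, r) for f, r in zip(out["fluc"], out["rluc"])]
    out["condition_mean"] = out.groupby("condition")["ratio"].transform("mean")
    return out


def performance_ratio(table: pd.DataFrame) -> pd.Series:
    """Per-gene U7smOPT-snRNA-to-cadRNA editing performance ratio.

    ratio = mean_edit_u7 / mean_edit_cad per gene; a zero cadRNA mean is
    an error naming the gene.
    """
    zero = table[table["mean_edit_cad"] <= 0]
    if not zero.empty:
        genes = ", ".join(zero["gene"].astype(str))
        raise ValueError(f"zero cadRNA mean editing for gene(s): {genes}")
    ratio = table["mean_edit_u7"] / table["mean_edit_cad"]
    ratio.index = pd.Index(table["gene"], name="gene")
    ratio.name = "performance_ratio"
    return ratio


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value.

    p is from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.  Requires
    n ≥ 3 and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    # product-moment form: exact ±1 on colinear integer-representable data
    a = x - x.mean()
    b = y - y.mean()
    r = float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))
    r = max(-1.0, min(1.0, r))
    if r * r >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p
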