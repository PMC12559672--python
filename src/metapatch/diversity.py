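"""Per-community diversity indices and pairwise dissimilarity.

Shannon-Wiener diversity uses the natural logarithm, which makes Pielou
evenness exactly H / ln(S). Pielou is undefined for communities with fewer
than two species; we return ``None`` rather than 0 so downstream averaging
can skip those communities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.stats import entropy as _entropy

from ._errors import UndefinedMetricError, ValidationError


@dataclass(frozen=True)
class DiversityProfile:
    """Summary indices for one community (one patch or subregion, one period)."""

    abundance: int
    richness: int
    shdi: float
    pielou: float | None


def diversity_profile(counts) -> DiversityProfile:
    """Compute abundance, richness, Shannon-Wiener H' and Pielou J'.

    Zero counts are excluded from the proportions. H' = -sum p_i ln p_i over
    species with positive counts; J' = H'/ln(S) when S >= 2, else None.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValidationError("empty count vector")
    if (x < 0).any():
        raise ValidationError("negative count in community vector")
    positive = x[x > 0]
    abundance = int(x.sum())
    richness = int(positive.size)
    if richness == 0:
        return DiversityProfile(0, 0, 0.0, None)
    shdi = float(_entropy(positive))  # normalizes and uses natural log
    pielou = float(shdi / np.log(richness)) if richness >= 2 else None
    return DiversityProfile(abundance, richness, shdi, pielou)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1].

    Raises :class:`UndefinedMetricError` when both communities are empty.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError("count vectors have different lengths")
    if (xa < 0).any() or (ya < 0).any():
        raise ValidationError("negative count in community vector")
    if xa.sum() == 0 and ya.sum() == 0:
        raise UndefinedMetricError(
            "Bray-Curtis undefined for two all-zero communities")
    return float(_braycurtis(xa, ya))
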