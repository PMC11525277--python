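"""End-to-end convenience pipeline: raw stacks -> combined drought index.

Wires the default indicator triple (SMCI for soil moisture, TCI for
temperature, SIWSI-1 for crop water stress) through normalization,
entropy weighting and combination.  The SIWSI orientation is flipped
during normalization (it increases with stress while the condition
indices increase with wetness) so that low index = drought uniformly;
pass ``flip_siwsi=False`` to disable.
"""

from __future__ import annotations

from dataclasses import dataclass

from regcdi.core import (CombinedIndexSeries, EntropyWeights,
                         NormalizedIndicator, combine_regcdi,
                         normalize_indicator, weights_from_stack)
from regcdi.grid import GriddedSeries
from regcdi.indicators import (ClimatologyGrid, compute_siwsi, compute_smci,
                               compute_tci)

__all__ = ["IndexResult", "default_index"]


@dataclass
class IndexResult:
    """The combined index with its constituents and weights."""

    index: CombinedIndexSeries
    indicators: list[NormalizedIndicator]
    weights: EntropyWeights


def default_index(ssm: GriddedSeries, lst: GriddedSeries,
                  swir: GriddedSeries, nir: GriddedSeries,
                  monthly_climatology: bool = True,
                  flip_siwsi: bool = True) -> IndexResult:
    """Combined index from the default SMCI / TCI / SIWSI-1 triple."""
    smci = compute_smci(ssm, ClimatologyGrid.from_series(ssm, monthly_climatology))
    tci = compute_tci(lst, ClimatologyGrid.from_series(lst, monthly_climatology))
    siwsi = compute_siwsi(swir, nir, variant=1)
    normalized = [
        normalize_indicator(smci),
        normalize_indicator(tci),
        normalize_indicator(siwsi, drought_is_high=flip_siwsi),
    ]
    weights = weights_from_stack(normalized)
    index = combine_regcdi(normalized, weights)
    return IndexResult(index=index, indicators=normalized, weights=weights)
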