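"""Concatenation of per-map radiomic vectors into per-patient feature vectors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import RadiomicVector

__all__ = ["CATEGORY_MAPS", "PatientFeatureVector", "assemble_vector"]

#: fixed map ordering of each data category
CATEGORY_MAPS = {
    "cmri": ("ceT1w", "FLAIR", "ADC", "CBV"),
    "oxymet": ("OEF", "CMRO2", "capiPO2", "mitoPO2"),
    "vam": ("uCBV", "MVD", "VSI", "MTI"),
    "oxyvam": ("OEF", "CMRO2", "capiPO2", "mitoPO2", "uCBV", "MVD", "VSI", "MTI"),
}


@dataclass
class PatientFeatureVector:
    """Concatenated, map-prefixed feature vector of one patient."""

    category: str
    names: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = 107 * len(CATEGORY_MAPS[self.category])
        if self.values.shape != (expected,):
            raise ValueError(f"category {self.category!r} expects {expected} features, "
                             f"got {self.values.shape}")


def assemble_vector(per_map: dict[str, RadiomicVector] | list[RadiomicVector],
                    category: str) -> PatientFeatureVector:
    """Concatenate the per-map vectors of a category in canonical map order.

    The input map order is irrelevant; missing maps are reported by name.
    """
    if category not in CATEGORY_MAPS:
        raise ValueError(f"unknown category {category!r}; choose from {tuple(CATEGORY_MAPS)}")
    if not isinstance(per_map, dict):
        per_map = {rv.source_map: rv for rv in per_map}
    missing = [m for m in CATEGORY_MAPS[category] if m not in per_map]
    if missing:
        raise ValueError(f"category {category!r} is missing map(s): {', '.join(missing)}")
    names, values = [], []
    for m in CATEGORY_MAPS[category]:
        rv = per_map[m]
        names.extend(f"{m}_{n}" for n in rv.names)
        values.append(rv.values)
    return PatientFeatureVector(category, tuple(names), np.concatenate(values))
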