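"""Probability-map cleanup: auto-thresholding and iterative region removal.

The raw forest output is a soft membrane probability map.  An automatic
global threshold (Otsu by default) turns it into a binary membrane map; a
rule-based pass then iteratively deletes connected foreground components
whose shape says "organelle" rather than "membrane" — membranes are thin,
elongated, low-solidity nets, while false positives from dark organelles are
small compact blobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import measure as skmeasure

REGION_PROPERTIES = ("area", "euler_number", "solidity", "eccentricity")
_COMPARATORS = {
    "<": np.less,
    ">": np.greater,
    "<=": np.less_equal,
    ">=": np.greater_equal,
}


@dataclass(frozen=True)
class RegionRule:
    """A removal rule: delete components whose ``property`` compares true
    against ``threshold``."""

    property: str
    comparator: str
    threshold: float

    def __post_init__(self):
        if self.property not in REGION_PROPERTIES:
            raise ValueError(
                f"property must be one of {REGION_PROPERTIES}, got {self.property!r}"
            )
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")

    def matches(self, values: dict[str, float]) -> bool:
        return bool(_COMPARATORS[self.comparator](values[self.property], self.threshold))


# A rule set is an OR of clauses; a clause is a single RegionRule or a
# conjunction (tuple) of RegionRules that must all hold.  Membranes are
# thin / low-solidity / high-eccentricity nets, so the defaults remove tiny
# specks and small compact blobs (organelle false positives).
Clause = RegionRule | tuple[RegionRule, ...]
DEFAULT_RULES: tuple[Clause, ...] = (
    RegionRule("area", "<", 100),
    (
        RegionRule("solidity", ">", 0.7),
        RegionRule("eccentricity", "<", 0.9),
        RegionRule("area", "<", 1000),
    ),
)


def auto_threshold(prob: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Binarize a probability map with a global automatic threshold.

    ``method`` is one of otsu / mean / isodata; foreground (1) marks
    membrane, i.e. values >= threshold.  A constant map has no separable
    classes and yields an all-background result.
    """
    prob = np.asarray(prob, dtype=np.float64)
    if np.ptp(prob) == 0:
        return np.zeros(prob.shape, dtype=np.uint8)
    if method == "otsu":
        t = skfilters.threshold_otsu(prob)
    elif method == "mean":
        t = skfilters.threshold_mean(prob)
    elif method == "isodata":
        t = skfilters.threshold_isodata(prob)
    else:
        raise ValueError(f"unknown auto-threshold method {method!r}")
    return (prob >= t).astype(np.uint8)


def _component_matches(props, rules) -> bool:
    values = {
        "area": float(props.area),
        "euler_number": float(props.euler_number),
        "solidity": float(props.solidity),
        "eccentricity": float(props.eccentricity),
    }
    for clause in rules:
        parts = clause if isinstance(clause, tuple) else (clause,)
        if all(rule.matches(values) for rule in parts):
            return True
    return False


def iterative_region_removal(
    binary: np.ndarray,
    rules: tuple[Clause, ...] = DEFAULT_RULES,
    max_iters: int = 10,
) -> np.ndarray:
    """Iteratively delete 8-connected foreground components matching any rule.

    Removal is component-atomic and monotone (foreground only shrinks);
    iteration stops at a fixpoint or after ``max_iters`` passes.
    """
    out = np.asarray(binary).astype(bool).copy()
    if not rules:
        return out.astype(np.uint8)
    struct = ndi.generate_binary_structure(2, 2)
    for _ in range(max_iters):
        labeled, n = ndi.label(out, structure=struct)
        if n == 0:
            break
        removed = False
        for props in skmeasure.regionprops(labeled):
            if _component_matches(props, rules):
                out[labeled == props.label] = False
                removed = True
        if not removed:
            break
    return out.astype(np.uint8)


def postprocess(
    prob: np.ndarray,
    method: str = "otsu",
    rules: tuple[Clause, ...] = DEFAULT_RULES,
    max_iters: int = 10,
) -> np.ndarray:
    """Full cleanup: auto-threshold then iterative region removal."""
    return iterative_region_removal(auto_threshold(prob, method), rules, max_iters)
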