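"""BI-RADS ordinal scale, sign-count mapping, and plane-fusion rules.

Breast lesions are rated on the five-level BI-RADS suspicion scale
{3, 4A, 4B, 4C, 5}.  A CAD system emits a dichotomous "possibly benign" /
"possibly malignant" call per imaging plane; two fusion rules aggregate
the per-plane calls into a lesion-level verdict:

* cross-planes  — 2 orthogonal planes, positive if >= 1 plane is malignant;
* quadri-planes — 4 planes (2 orthogonal + 2 oblique at 45 degrees),
  positive if >= k planes are malignant (k = 2 by default).

A positive fused verdict upgrades a reader's BI-RADS category by one level
(saturating at 5); an all-benign plane set downgrades by one level
(saturating at 3).  A quadri-planes set with exactly one malignant plane is
neutral and leaves the category unchanged.  Lesion-level positivity is
"category 4B or higher".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "BiradsCategory",
    "BinaryVerdict",
    "Plane",
    "PlaneVerdict",
    "PlaneCall",
    "PlaneCallSet",
    "SignProfile",
    "FusionRule",
    "CROSS_PLANES",
    "QUADRI_PLANES",
    "signs_to_category",
    "dichotomize_category",
    "cad_standalone_verdict",
    "adjust_category",
    "combined_mode_verdict",
]


class BiradsCategory(enum.IntEnum):
    """Ordinal BI-RADS category; integer value is the rank on the scale.

    Rank 0 is category 3 (probably benign, <2% malignancy likelihood);
    rank 4 is category 5 (>95% likelihood).  Category 4 is subdivided into
    4A/4B/4C (2-10%, 10-50%, 50-95%).
    """

    C3 = 0
    C4A = 1
    C4B = 2
    C4C = 3
    C5 = 4

    @property
    def label(self) -> str:
        return _CATEGORY_LABELS[self]

    @property
    def rank(self) -> int:
        return int(self)

    @classmethod
    def from_label(cls, label: str) -> "BiradsCategory":
        try:
            return _CATEGORY_BY_LABEL[str(label).strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown BI-RADS category {label!r}; expected one of "
                f"{sorted(_CATEGORY_BY_LABEL)}"
            ) from None

    def shifted(self, delta: int) -> "BiradsCategory":
        """Category ``delta`` levels away, saturating at the scale ends."""
        return BiradsCategory(min(4, max(0, self.rank + delta)))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


_CATEGORY_LABELS = {
    BiradsCategory.C3: "3",
    BiradsCategory.C4A: "4A",
    BiradsCategory.C4B: "4B",
    BiradsCategory.C4C: "4C",
    BiradsCategory.C5: "5",
}
_CATEGORY_BY_LABEL = {v: k for k, v in _CATEGORY_LABELS.items()}

#: Lowest category dichotomized as positive for cancer.
POSITIVE_THRESHOLD = BiradsCategory.C4B


class BinaryVerdict(enum.Enum):
    """Dichotomous lesion-level diagnosis."""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    def __bool__(self) -> bool:
        return self is BinaryVerdict.POSITIVE


class Plane(enum.Enum):
    """Imaging plane of a stored CAD frame.

    The two oblique planes are acquired by rotating the probe 45 degrees
    around the lesion center; which rotation direction maps to which label
    is conventional.
    """

    LONGITUDINAL = "longitudinal"
    TRANSVERSE = "transverse"
    OBLIQUE_A = "oblique_a"
    OBLIQUE_B = "oblique_b"


#: Planes a 2-plane (cross) acquisition must contain.
CROSS_PLANE_SET = frozenset({Plane.LONGITUDINAL, Plane.TRANSVERSE})


class PlaneVerdict(enum.Enum):
    """Per-plane dichotomous CAD output."""

    POSSIBLY_BENIGN = "B"
    POSSIBLY_MALIGNANT = "M"

    @classmethod
    def from_code(cls, code: str) -> "PlaneVerdict":
        code = str(code).strip().upper()
        if code in ("M", "POSSIBLY_MALIGNANT", "MALIGNANT"):
            return cls.POSSIBLY_MALIGNANT
        if code in ("B", "POSSIBLY_BENIGN", "BENIGN"):
            return cls.POSSIBLY_BENIGN
        raise ValueError(f"unknown plane verdict {code!r}; expected 'M' or 'B'")


@dataclass(frozen=True)
class PlaneCall:
    plane: Plane
    verdict: PlaneVerdict


@dataclass(frozen=True)
class PlaneCallSet:
    """Per-lesion collection of CAD plane calls (2 = cross, 4 = quadri)."""

    lesion_id: str
    calls: tuple[PlaneCall, ...]

    def __post_init__(self) -> None:
        calls = tuple(self.calls)
        object.__setattr__(self, "calls", calls)
        if len(calls) not in (2, 4):
            raise ValueError(
                f"lesion {self.lesion_id}: expected 2 or 4 plane calls, got {len(calls)}"
            )
        planes = [c.plane for c in calls]
        if len(set(planes)) != len(planes):
            raise ValueError(f"lesion {self.lesion_id}: duplicate plane labels")
        if len(calls) == 2 and set(planes) != CROSS_PLANE_SET:
            raise ValueError(
                f"lesion {self.lesion_id}: 2-plane sets must hold the "
                "longitudinal and transverse planes"
            )

    @property
    def n_planes(self) -> int:
        return len(self.calls)

    @property
    def n_malignant(self) -> int:
        """Number of planes called possibly malignant."""
        return sum(
            1 for c in self.calls if c.verdict is PlaneVerdict.POSSIBLY_MALIGNANT
        )

    def subset(self, planes: Iterable[Plane]) -> "PlaneCallSet":
        wanted = set(planes)
        return PlaneCallSet(
            self.lesion_id, tuple(c for c in self.calls if c.plane in wanted)
        )

    @classmethod
    def from_codes(cls, lesion_id: str, codes: Sequence[str]) -> "PlaneCallSet":
        """Build from 'M'/'B' codes ordered long, trans[, oblique_a, oblique_b]."""
        order = (Plane.LONGITUDINAL, Plane.TRANSVERSE, Plane.OBLIQUE_A, Plane.OBLIQUE_B)
        if len(codes) > len(order):
            raise ValueError(f"lesion {lesion_id}: too many plane calls")
        return cls(
            lesion_id,
            tuple(
                PlaneCall(p, PlaneVerdict.from_code(c))
                for p, c in zip(order[: len(codes)], codes, strict=True)
            ),
        )


@dataclass(frozen=True)
class SignProfile:
    """Count of malignant ultrasound features observed on a lesion.

    Malignant signs include irregular shape, antiparallel orientation,
    noncircumscribed margin, microcalcification, acoustic halo, posterior
    shadowing and abnormalities of the surrounding tissue.
    """

    n_malignant_signs: int

    def __post_init__(self) -> None:
        if self.n_malignant_signs < 0:
            raise ValueError("n_malignant_signs must be >= 0")


@dataclass(frozen=True)
class FusionRule:
    """k-of-n fusion of per-plane CAD calls into one lesion verdict."""

    method: str
    k_positive: int = field(default=0)

    _N_PLANES = {"cross_planes": 2, "quadri_planes": 4}
    _DEFAULT_K = {"cross_planes": 1, "quadri_planes": 2}

    def __post_init__(self) -> None:
        if self.method not in self._N_PLANES:
            raise ValueError(
                f"unknown fusion method {self.method!r}; "
                f"expected one of {sorted(self._N_PLANES)}"
            )
        if self.k_positive == 0:
            object.__setattr__(self, "k_positive", self._DEFAULT_K[self.method])
        if not 1 <= self.k_positive <= self.n_planes:
            raise ValueError(
                f"k_positive must lie in [1, {self.n_planes}] for {self.method}"
            )

    @property
    def n_planes(self) -> int:
        return self._N_PLANES[self.method]


CROSS_PLANES = FusionRule("cross_planes", 1)
QUADRI_PLANES = FusionRule("quadri_planes", 2)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def signs_to_category(profile: SignProfile) -> BiradsCategory:
    """Map a malignant-sign count to a BI-RADS category.

    0 signs -> 3, then 1/2/3 signs -> 4A/4B/4C, and 4 or more -> 5.  The
    mapping is monotone non-decreasing in the count.
    """
    return BiradsCategory(min(profile.n_malignant_signs, 4))


def dichotomize_category(cat: BiradsCategory) -> BinaryVerdict:
    """Positive for cancer iff the category is 4B, 4C or 5."""
    if cat >= POSITIVE_THRESHOLD:
        return BinaryVerdict.POSITIVE
    return BinaryVerdict.NEGATIVE


def _check_rule(calls: PlaneCallSet, rule: FusionRule) -> None:
    if calls.n_planes != rule.n_planes:
        raise ValueError(
            f"lesion {calls.lesion_id}: {rule.method} needs {rule.n_planes} "
            f"plane calls, got {calls.n_planes}"
        )


def cad_standalone_verdict(calls: PlaneCallSet, rule: FusionRule) -> BinaryVerdict:
    """Fused CAD verdict: positive iff >= k planes are possibly malignant."""
    _check_rule(calls, rule)
    if calls.n_malignant >= rule.k_positive:
        return BinaryVerdict.POSITIVE
    return BinaryVerdict.NEGATIVE


def adjust_category(
    cat: BiradsCategory, calls: PlaneCallSet, rule: FusionRule
) -> BiradsCategory:
    """Shift a reader's category by the fused CAD verdict.

    Positive fused verdict: one level up; all planes benign: one level down;
    otherwise (quadri-planes with exactly one malignant plane) unchanged.
    Saturates at categories 3 and 5; the output never differs from the input
    by more than one level.
    """
    _check_rule(calls, rule)
    m = calls.n_malignant
    if m >= rule.k_positive:
        return cat.shifted(+1)
    if m == 0:
        return cat.shifted(-1)
    return cat


def combined_mode_verdict(
    cat: BiradsCategory, calls: PlaneCallSet, rule: FusionRule
) -> BinaryVerdict:
    """Reader-plus-CAD verdict: dichotomize the CAD-adjusted category."""
    return dichotomize_category(adjust_category(cat, calls, rule))
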