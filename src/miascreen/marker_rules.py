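"""Marker positivity thresholds and the software-independent index-assay vote.

The multivariate index assay (MIA) panels CA 125, beta-2 microglobulin,
transferrin, apolipoprotein A1 and prealbumin (transthyretin).  Without the
proprietary scoring software, the panel is scored by a simple vote: a marker
is positive when it falls outside its reference range in the direction
associated with malignancy (CA 125 and beta-2 microglobulin above the upper
limit; transferrin, ApoA1 and prealbumin below the lower limit), and the
panel is high risk when at least three of the five markers are positive.

CA 125 cutoffs are menopause dependent (> 200 IU/L premenopausal, > 35 IU/L
postmenopausal, the gynecologic-oncology referral criteria).  All boundary
comparisons are strict: a value exactly at a limit is within the normal
range.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .cohort_model import MARKER_NAMES, MarkerPanel, MenopausalStatus

__all__ = [
    "MarkerThresholds",
    "MarkerCall",
    "MiaResult",
    "MissingMarkerError",
    "DEFAULT_THRESHOLDS",
    "classify_marker",
    "mia_classify",
    "ca125_classify",
    "combine_parallel",
]

MIA_VOTES_REQUIRED = 3  # >= 3 of 5 positive markers -> high risk


class MissingMarkerError(ValueError):
    """The index assay is undefined when any marker value is absent."""

    def __init__(self, markers: tuple[str, ...]):
        self.markers = markers
        super().__init__(f"missing marker value(s): {', '.join(markers)}")


@dataclass(frozen=True)
class MarkerThresholds:
    """Laboratory reference-range limits used for positivity calls.

    Units: IU/L for CA 125, g/L otherwise.  Only the limits on the
    malignancy side of each range drive classification; the opposite bounds
    are retained for documentation of the full kit reference ranges.
    """

    ca125_premenopausal_upper: float = 200.0
    ca125_postmenopausal_upper: float = 35.0
    b2m_upper: float = 2.46
    transferrin_lower: float = 2.24
    apoa1_lower: float = 1.24
    prealbumin_lower: float = 0.216
    # documentation-only opposite bounds of the two-sided kit ranges
    b2m_lower: float = 1.22
    transferrin_upper: float = 4.06
    apoa1_upper: float = 2.02
    prealbumin_upper: float = 0.328

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")
        for lower, upper in (
            (self.b2m_lower, self.b2m_upper),
            (self.transferrin_lower, self.transferrin_upper),
            (self.apoa1_lower, self.apoa1_upper),
            (self.prealbumin_lower, self.prealbumin_upper),
        ):
            if not lower < upper:
                raise ValueError(f"range lower bound {lower} must be < upper {upper}")

    def ca125_upper(self, status: MenopausalStatus) -> float:
        if status is MenopausalStatus.PREMENOPAUSAL:
            return self.ca125_premenopausal_upper
        return self.ca125_postmenopausal_upper

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerThresholds":
        """Load thresholds from a YAML mapping; absent keys keep defaults."""
        with Path(path).open(encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: thresholds file must be a mapping")
        unknown = set(data) - set(asdict(cls()))
        if unknown:
            raise ValueError(f"{path}: unknown threshold keys {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)


DEFAULT_THRESHOLDS = MarkerThresholds()


@dataclass(frozen=True)
class MarkerCall:
    marker: str
    value: float
    positive: bool


@dataclass(frozen=True)
class MiaResult:
    """Outcome of the 3-of-5 vote on one patient's panel."""

    calls: tuple[MarkerCall, ...]
    n_positive: int
    high_risk: bool


def classify_marker(
    marker: str,
    value: float | None,
    menopausal_status: MenopausalStatus,
    thresholds: MarkerThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Positivity of a single marker (strict comparison against its limit)."""
    if marker not in MARKER_NAMES:
        raise ValueError(f"unknown marker {marker!r}; expected one of {MARKER_NAMES}")
    if value is None:
        raise MissingMarkerError((marker,))
    if value < 0:
        raise ValueError(f"marker {marker} value must be >= 0, got {value}")
    if marker == "ca125":
        return value > thresholds.ca125_upper(menopausal_status)
    if marker == "b2m":
        return value > thresholds.b2m_upper
    if marker == "transferrin":
        return value < thresholds.transferrin_lower
    if marker == "apoa1":
        return value < thresholds.apoa1_lower
    return value < thresholds.prealbumin_lower


def mia_classify(
    panel: MarkerPanel,
    menopausal_status: MenopausalStatus,
    thresholds: MarkerThresholds = DEFAULT_THRESHOLDS,
) -> MiaResult:
    """Score the five-marker panel with the 3-of-5 positivity vote.

    High risk of malignancy when at least three markers are positive, low
    risk when two or fewer.  All five values must be present; the vote is
    never silently degraded to a smaller panel.
    """
    missing = panel.missing()
    if missing:
        raise MissingMarkerError(missing)
    calls = tuple(
        MarkerCall(
            marker=name,
            value=getattr(panel, name),
            positive=classify_marker(
                name, getattr(panel, name), menopausal_status, thresholds
            ),
        )
        for name in MARKER_NAMES
    )
    n_positive = sum(call.positive for call in calls)
    return MiaResult(
        calls=calls,
        n_positive=n_positive,
        high_risk=n_positive >= MIA_VOTES_REQUIRED,
    )


def ca125_classify(
    ca125: float | None,
    menopausal_status: MenopausalStatus,
    thresholds: MarkerThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Standalone CA 125 call: suspicious when strictly above the
    menopause-specific referral cutoff (200 IU/L pre-, 35 IU/L
    postmenopausal)."""
    return classify_marker("ca125", ca125, menopausal_status, thresholds)


def combine_parallel(result_a: bool, result_b: bool) -> bool:
    """Parallel combination of two tests: positive if either is positive."""
    return bool(result_a) or bool(result_b)
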