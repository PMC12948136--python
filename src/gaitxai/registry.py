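"""Static domain registries: the 52-marker set, modality layouts, speed classes.

The optical marker set follows the standard full-body placement used by the
public multimodal gait cohort this package emulates: pelvis, thigh/shank,
foot, trunk, shoulder girdle and arm landmarks on both sides. Marker
trajectories flatten marker-major: channel ``c`` (0-based) belongs to marker
``c // 3 + 1`` (1-based) and coordinate ``c % 3`` (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MarkerEntry", "MarkerRegistry", "ModalitySpec", "SpeedClass",
    "MODALITY_SPECS", "SPEED_CLASSES", "default_marker_registry",
    "scaled_modality_specs",
]

COORDS = ("x", "y", "z")


@dataclass(frozen=True)
class MarkerEntry:
    index: int          # 1-based position in the registry
    label: str
    description: str
    side: str           # "L", "R" or "M" (midline)
    region: str         # pelvis / leg / foot / trunk / shoulder / arm


# (label, description, side, region) in registry order
_MARKER_TABLE = [
    ("L_IAS", "Left anterior-superior iliac spine", "L", "pelvis"),
    ("L_IPS", "Left posterior-superior iliac spine", "L", "pelvis"),
    ("L_FTC", "Left greater trochanter", "L", "leg"),
    ("L_FLE", "Left lateral femoral epicondyle", "L", "leg"),
    ("L_FME", "Left medial femoral epicondyle", "L", "leg"),
    ("L_FAX", "Left fibula head", "L", "leg"),
    ("L_TTC", "Left tibial tuberosity", "L", "leg"),
    ("L_FAL", "Left lateral tibial malleolus", "L", "leg"),
    ("L_TAM", "Left medial tibial malleolus", "L", "leg"),
    ("L_FCC", "Left posterior calcaneus", "L", "foot"),
    ("L_FM1", "Left 1st metatarsal head", "L", "foot"),
    ("L_FM2", "Left 2nd metatarsal head", "L", "foot"),
    ("L_FM5", "Left 5th metatarsal head", "L", "foot"),
    ("CV7", "7th cervical vertebra", "M", "trunk"),
    ("SXS", "Suprasternal notch", "M", "trunk"),
    ("L_SIA", "Left acromial tip", "L", "shoulder"),
    ("L_SRS", "Left spine root", "L", "shoulder"),
    ("L_SAA", "Left acromial angle", "L", "shoulder"),
    ("L_SAE", "Left acromial edge", "L", "shoulder"),
    ("L_HLE", "Left lateral humerus epicondyle", "L", "arm"),
    ("L_HME", "Left medial humerus epicondyle", "L", "arm"),
    ("L_UOA", "Apex of the left olecranon", "L", "arm"),
    ("L_RSP", "Left radius styloid process", "L", "arm"),
    ("L_UHE", "Left ulnar styloid process", "L", "arm"),
    ("L_HM2", "Left head of the 2nd metacarpus", "L", "arm"),
    ("L_HM5", "Left head of the 5th metacarpus", "L", "arm"),
    ("R_IPS", "Right posterior-superior iliac spine", "R", "pelvis"),
    ("R_IAS", "Right anterior-superior iliac spine", "R", "pelvis"),
    ("R_FTC", "Right greater trochanter", "R", "leg"),
    ("R_FLE", "Right lateral femoral epicondyle", "R", "leg"),
    ("R_FME", "Right medial femoral epicondyle", "R", "leg"),
    ("R_FAX", "Right fibula head", "R", "leg"),
    ("R_TTC", "Right tibial tuberosity", "R", "leg"),
    ("R_FAL", "Right lateral tibial malleolus", "R", "leg"),
    ("R_TAM", "Right medial tibial malleolus", "R", "leg"),
    ("R_FCC", "Right posterior calcaneus", "R", "foot"),
    ("R_FM1", "Right 1st metatarsal head", "R", "foot"),
    ("R_FM2", "Right 2nd metatarsal head", "R", "foot"),
    ("R_FM5", "Right 5th metatarsal head", "R", "foot"),
    ("TV10", "Spinous process of the 10th thoracic vertebra", "M", "trunk"),
    ("SJN", "Xiphoid process", "M", "trunk"),
    ("R_SIA", "Right acromial tip", "R", "shoulder"),
    ("R_SRS", "Right spine root", "R", "shoulder"),
    ("R_SAA", "Right acromial angle", "R", "shoulder"),
    ("R_SAE", "Right acromial edge", "R", "shoulder"),
    ("R_HLE", "Right lateral humerus epicondyle", "R", "arm"),
    ("R_HME", "Right medial humerus epicondyle", "R", "arm"),
    ("R_UOA", "Apex of the right olecranon", "R", "arm"),
    ("R_RSP", "Right radius styloid process", "R", "arm"),
    ("R_UHE", "Right ulnar styloid process", "R", "arm"),
    ("R_HM2", "Right head of the 2nd metacarpus", "R", "arm"),
    ("R_HM5", "Right head of the 5th metacarpus", "R", "arm"),
]


class MarkerRegistry:
    """Ordered full-body marker set with the marker/channel flattening rule."""

    def __init__(self, entries=None):
        if entries is None:
            entries = [MarkerEntry(i + 1, *row)
                       for i, row in enumerate(_MARKER_TABLE)]
        self.entries = list(entries)
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("marker labels must be unique")

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, marker_index: int) -> MarkerEntry:
        """Lookup by 1-based marker index."""
        return self.entries[marker_index - 1]

    def by_label(self, label: str) -> MarkerEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def n_channels(self) -> int:
        return 3 * len(self.entries)

    def channel_of(self, marker_index: int, coord: int) -> int:
        """0-based channel for (1-based marker, coordinate 0..2)."""
        if not 1 <= marker_index <= len(self.entries):
            raise IndexError(f"marker index {marker_index} outside registry")
        if not 0 <= coord <= 2:
            raise IndexError("coordinate must be 0, 1 or 2")
        return 3 * (marker_index - 1) + coord

    def marker_of_channel(self, channel: int) -> tuple[int, int]:
        """Inverse flattening: 0-based channel -> (1-based marker, coord)."""
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} outside registry span")
        return channel // 3 + 1, channel % 3

    def channels_of_markers(self, marker_indices) -> list[int]:
        return [self.channel_of(m, d) for m in marker_indices for d in range(3)]

    def channel_labels(self) -> list[str]:
        return [f"{e.label}_{c}" for e in self.entries for c in COORDS]


def default_marker_registry() -> MarkerRegistry:
    return MarkerRegistry()


@dataclass(frozen=True)
class ModalitySpec:
    name: str        # markers / grf / emg / fm
    rate: float      # source sampling rate, Hz
    temporal: int    # frames per (padded) trial
    dim: int         # coordinates per physical point
    spatial: int     # channels

    @property
    def shape(self) -> tuple[int, int]:
        return (self.temporal, self.spatial)


MODALITY_SPECS: dict[str, ModalitySpec] = {
    "markers": ModalitySpec("markers", 100.0, 585, 3, 156),
    "grf": ModalitySpec("grf", 1500.0, 585, 3, 24),
    "emg": ModalitySpec("emg", 1500.0, 8985, 1, 8),
    "fm": ModalitySpec("fm", 1500.0, 8985, 3, 12),
}


def scaled_modality_specs(factor: int) -> dict[str, ModalitySpec]:
    """Registry with temporal lengths divided by ``factor``.

    Used to run the full pipeline at miniature problem sizes in tests; the
    channel layout (and hence all channel semantics) is unchanged.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer divisor")
    factor = int(factor)
    return {
        name: ModalitySpec(s.name, s.rate / factor,
                           int(max(8, s.temporal // factor)), s.dim, s.spatial)
        for name, s in MODALITY_SPECS.items()
    }


@dataclass(frozen=True)
class SpeedClass:
    index: int
    label: str
    speed_range: tuple[float, float]   # m/s, (low, high]


# Class 2 merges the moderate and self-selected natural-speed conditions;
# the fast-preferred upper bound is a configurable convention.
SPEED_CLASSES: tuple[SpeedClass, ...] = (
    SpeedClass(0, "very slow", (0.0, 0.4)),
    SpeedClass(1, "slow", (0.4, 0.8)),
    SpeedClass(2, "moderate/self-selected", (0.8, 1.2)),
    SpeedClass(3, "fast preferred", (1.2, 1.8)),
)


def speed_classes(fast_range: tuple[float, float] = (1.2, 1.8)):
    """The four speed classes, with a configurable fast-preferred range."""
    classes = list(SPEED_CLASSES[:3])
    if fast_range[0] < SPEED_CLASSES[2].speed_range[1]:
        raise ValueError("fast range must start at or above 1.2 m/s")
    classes.append(SpeedClass(3, "fast preferred", tuple(fast_range)))
    return tuple(classes)
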