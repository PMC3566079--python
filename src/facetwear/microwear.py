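"""2D microwear counting: the seven classical variables.

Features inside the standard 300x300 µm counting square outlined on the
centre of the wear facet are tallied into Np (pits), Np5/Np10 (pits with
major-axis diameter > 5/10 µm), Ns (scratches), Nws5/Nws10 (scratches
wider than 5/10 µm) and Ls (mean scratch length, µm). The classical visual
pit/scratch distinction is replaced by a reproducible aspect-ratio rule:
a feature is a scratch iff length/width >= 4.
"""

from __future__ import annotations

from dataclasses import dataclass

from facetwear.synthetic import SurfaceFeature, PIT_SCRATCH_ASPECT

__all__ = ["MicrowearCounts", "classify_feature", "count_microwear",
           "DEFAULT_SQUARE_UM"]

DEFAULT_SQUARE_UM = 300.0


@dataclass
class MicrowearCounts:
    """The seven microwear variables for one facet.

    ``Ls_um`` is None (flagged undefined) when no scratch was counted.
    """

    Np: int = 0
    Np5: int = 0
    Np10: int = 0
    Ns: int = 0
    Nws5: int = 0
    Nws10: int = 0
    Ls_um: float | None = None

    def as_dict(self) -> dict:
        return {"Np": self.Np, "Np5": self.Np5, "Np10": self.Np10,
                "Ns": self.Ns, "Nws5": self.Nws5, "Nws10": self.Nws10,
                "Ls": self.Ls_um}


def classify_feature(feature: SurfaceFeature,
                     aspect_threshold: float = PIT_SCRATCH_ASPECT) -> str:
    """Classify a feature as ``pit`` or ``scratch`` by its aspect ratio.

    Scratch iff length/width >= threshold (default 4; boundary counts as
    scratch).
    """
    if aspect_threshold <= 1:
        raise ValueError("aspect_threshold must exceed 1")
    if feature.length_um <= 0 or feature.width_um <= 0:
        raise ValueError("feature dimensions must be positive")
    return ("scratch"
            if feature.length_um / feature.width_um >= aspect_threshold
            else "pit")


def count_microwear(features, square_um: float = DEFAULT_SQUARE_UM,
                    center=None,
                    aspect_threshold: float = PIT_SCRATCH_ASPECT
                    ) -> MicrowearCounts:
    """Tally the seven microwear variables inside the counting square.

    A feature is counted iff its centre lies inside the square (inclusive
    on the lower/left edges, exclusive on the upper/right). Pit "diameter"
    is the feature's major axis; scratch width is its minor axis. With
    *center* None the square is centred on the feature field's bounding
    region midpoint ``(side/2, side/2)`` of a field generated by
    :func:`facetwear.synthetic.generate_counting_features`.
    """
    if square_um <= 0:
        raise ValueError("square_um must be positive")
    if center is None:
        from facetwear.synthetic import COUNTING_SQUARE_UM, _FIELD_MARGIN
        c = COUNTING_SQUARE_UM * _FIELD_MARGIN / 2.0
        center = (c, c)
    cx, cy = center
    half = square_um / 2.0
    counts = MicrowearCounts()
    lengths = []
    for f in features:
        if not (cx - half <= f.center_x < cx + half
                and cy - half <= f.center_y < cy + half):
            continue
        if classify_feature(f, aspect_threshold) == "scratch":
            counts.Ns += 1
            lengths.append(f.length_um)
            if f.width_um > 5.0:
                counts.Nws5 += 1
            if f.width_um > 10.0:
                counts.Nws10 += 1
        else:
            counts.Np += 1
            if f.length_um > 5.0:
                counts.Np5 += 1
            if f.length_um > 10.0:
                counts.Np10 += 1
    counts.Ls_um = (sum(lengths) / len(lengths)) if lengths else None
    return counts
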