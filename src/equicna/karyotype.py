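"""Sex-chromosome karyotype descriptions for the domestic horse.

The normal horse complement is 64 chromosomes (62 autosomes + XX or XY).
Copy-number aberrations of the sex pair are described here by the number of
X and Y copies of the main cell line, plus an optional second line for
mosaics (one zygote, post-zygotic gain/loss) and chimeras (two zygotes,
e.g. blood chimerism).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = ["KaryotypeSpec", "KARYOTYPES"]

_COMPONENT = re.compile(r"^(\d+),(X+)(Y*)$")


def _parse_component(comp: str) -> tuple[int, int, int]:
    m = _COMPONENT.match(comp.strip())
    if not m:
        raise ValueError(f"cannot parse karyotype component {comp!r}")
    total, xs, ys = int(m.group(1)), len(m.group(2)), len(m.group(3))
    if total != 62 + xs + ys:
        raise ValueError(
            f"{comp!r}: chromosome total {total} inconsistent with "
            f"{xs} X and {ys} Y copies (62 autosomes assumed)"
        )
    return total, xs, ys


@dataclass(frozen=True)
class KaryotypeSpec:
    """One (possibly mixed) sex-chromosome complement.

    Attributes
    ----------
    label : str
        Standard nomenclature, e.g. ``"64,XY"``, ``"65,XXY"``, ``"63,X"``,
        ``"63,X/64,XX"`` (mosaic) or ``"64,XX/64,XY chimera"``.
    x_copies, y_copies : int
        Sex-chromosome copies of the main cell line.
    mosaic_fraction : float
        Fraction of cells carrying the alternate line (0 = pure).
    alt_x_copies, alt_y_copies : int or None
        Copies in the alternate line; ignored when ``mosaic_fraction`` is 0.
    chimera : bool
        True when the two lines come from distinct zygotes (independent
        founder genotypes); False for a mosaic (shared zygote).
    """

    label: str
    x_copies: int
    y_copies: int
    mosaic_fraction: float = 0.0
    alt_x_copies: Optional[int] = None
    alt_y_copies: Optional[int] = None
    chimera: bool = False

    def __post_init__(self):
        if self.x_copies < 0 or self.y_copies < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.x_copies == 0 and self.y_copies == 0:
            raise ValueError("no viable karyotype: zero X and zero Y copies")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must be within [0, 1]")
        if self.mosaic_fraction > 0:
            if self.alt_x_copies is None or self.alt_y_copies is None:
                raise ValueError("mixed karyotype requires alternate copy numbers")
            if self.alt_x_copies == 0 and self.alt_y_copies == 0:
                raise ValueError("alternate line has zero X and zero Y copies")
        self._check_label()

    def _check_label(self):
        comps = [c.strip() for c in self.label.replace("chimera", "").split("/")]
        t, xs, ys = _parse_component(comps[0])
        if (xs, ys) != (self.x_copies, self.y_copies):
            raise ValueError(
                f"label {self.label!r} inconsistent with x={self.x_copies}, y={self.y_copies}"
            )
        if len(comps) > 1 and self.mosaic_fraction > 0:
            t2, xs2, ys2 = _parse_component(comps[1])
            if (xs2, ys2) != (self.alt_x_copies, self.alt_y_copies):
                raise ValueError(
                    f"label {self.label!r} inconsistent with alternate line "
                    f"x={self.alt_x_copies}, y={self.alt_y_copies}"
                )

    @property
    def mixed(self) -> bool:
        return self.mosaic_fraction > 0.0

    @property
    def lines(self) -> list[tuple[int, int, float]]:
        """Cell lines as (x_copies, y_copies, fraction)."""
        if not self.mixed:
            return [(self.x_copies, self.y_copies, 1.0)]
        return [
            (self.x_copies, self.y_copies, 1.0 - self.mosaic_fraction),
            (self.alt_x_copies, self.alt_y_copies, self.mosaic_fraction),
        ]

    @classmethod
    def from_label(
        cls, label: str, mosaic_fraction: float = 0.5, chimera: Optional[bool] = None
    ) -> "KaryotypeSpec":
        """Build a spec from standard nomenclature.

        For mixed labels (``"a/b"``) the second component becomes the
        alternate line at ``mosaic_fraction``; a trailing ``"chimera"``
        marks distinct zygotes.
        """
        is_chim = "chimera" in label if chimera is None else chimera
        comps = [c.strip() for c in label.replace("chimera", "").split("/")]
        _, xs, ys = _parse_component(comps[0])
        if len(comps) == 1:
            return cls(label, xs, ys)
        _, ax, ay = _parse_component(comps[1])
        return cls(label, xs, ys, mosaic_fraction, ax, ay, is_chim)


KARYOTYPES = {
    "64,XX": KaryotypeSpec("64,XX", 2, 0),
    "64,XY": KaryotypeSpec("64,XY", 1, 1),
    "63,X": KaryotypeSpec("63,X", 1, 0),
    "65,XXY": KaryotypeSpec("65,XXY", 2, 1),
    "65,XXX": KaryotypeSpec("65,XXX", 3, 0),
    "63,X/64,XX": KaryotypeSpec("63,X/64,XX", 1, 0, 0.5, 2, 0, False),
    "64,XY/65,XXY": KaryotypeSpec("64,XY/65,XXY", 1, 1, 0.5, 2, 1, False),
    "64,XX/64,XY chimera": KaryotypeSpec("64,XX/64,XY chimera", 2, 0, 0.5, 1, 1, True),
}
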