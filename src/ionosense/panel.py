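"""Marker panel: positions and source-population allele frequencies."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MarkerPanel", "default_marker_panel"]


@dataclass(frozen=True)
class MarkerPanel:
    """Biallelic markers with per-source alternate-allele frequencies.

    Positions are genetic (morgans), strictly increasing. ``f_alt_afr`` and
    ``f_alt_eas`` give the alternate-allele frequency of each marker in the
    African and East Asian source populations.
    """

    positions_morgans: np.ndarray
    f_alt_afr: np.ndarray
    f_alt_eas: np.ndarray
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_morgans, dtype=float)
        fa = np.asarray(self.f_alt_afr, dtype=float)
        fe = np.asarray(self.f_alt_eas, dtype=float)
        if len(pos) < 1:
            raise ValueError("panel must contain at least one marker")
        if not (len(pos) == len(fa) == len(fe)):
            raise ValueError("panel arrays must have equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        for f in (fa, fe):
            if np.any((f < 0) | (f > 1)):
                raise ValueError("allele frequencies must lie in [0, 1]")
        object.__setattr__(self, "positions_morgans", pos)
        object.__setattr__(self, "f_alt_afr", fa)
        object.__setattr__(self, "f_alt_eas", fe)
        if not self.ids:
            object.__setattr__(
                self, "ids", tuple(f"m{i:05d}" for i in range(len(pos)))
            )
        elif len(self.ids) != len(pos):
            raise ValueError("ids length mismatch")

    def __len__(self) -> int:
        return len(self.positions_morgans)

    def nearest_index(self, position_morgans: float) -> int:
        return int(np.argmin(np.abs(self.positions_morgans - position_morgans)))


def default_marker_panel(
    n_markers: int = 200,
    length_morgans: float = 0.5,
    f_alt_afr: float = 0.9,
    f_alt_eas: float = 0.1,
) -> MarkerPanel:
    """Evenly spaced diagnostic panel, emulating an ancestry-informative
    selection from a dense genotyping chip over one chromosomal window.

    Defaults (200 markers over 0.5 morgans, |f_afr - f_eas| = 0.8) reflect
    the regime local-ancestry callers operate in for deeply diverged source
    populations: sub-centimorgan marker spacing and strongly differentiated
    alleles."""
    pos = (np.arange(n_markers) + 0.5) * (length_morgans / n_markers)
    return MarkerPanel(
        positions_morgans=pos,
        f_alt_afr=np.full(n_markers, f_alt_afr),
        f_alt_eas=np.full(n_markers, f_alt_eas),
    )
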