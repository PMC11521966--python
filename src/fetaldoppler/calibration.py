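"""Physical calibration of a spectral Doppler raster.

The spectrogram is a raster whose columns index time and whose rows index
blood velocity relative to a zero line.  Rows increase downward, so a pixel
above the zero line carries positive velocity:

    velocity(row) = (zero_line_row - row) * vel_per_px      [cm/s]
    time(col)     = col * time_per_px                        [ms]
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class Calibration:
    """Maps raster coordinates to physical units.

    Parameters
    ----------
    time_per_px : float
        Milliseconds spanned by one column.
    vel_per_px : float
        cm/s spanned by one row.
    zero_line_row : float
        Row index (0-based) of the Doppler zero line.
    """

    time_per_px: float
    vel_per_px: float
    zero_line_row: float

    def __post_init__(self) -> None:
        if self.time_per_px <= 0:
            raise ValueError(f"time_per_px must be > 0, got {self.time_per_px}")
        if self.vel_per_px <= 0:
            raise ValueError(f"vel_per_px must be > 0, got {self.vel_per_px}")
        if self.zero_line_row < 0:
            raise ValueError(
                f"zero_line_row must be >= 0, got {self.zero_line_row}"
            )

    # ---- coordinate transforms -------------------------------------------
    def row_to_velocity(self, row):
        return (self.zero_line_row - row) * self.vel_per_px

    def velocity_to_row(self, v):
        return self.zero_line_row - v / self.vel_per_px

    def col_to_time(self, col):
        return col * self.time_per_px

    def time_to_col(self, t_ms):
        return t_ms / self.time_per_px

    def rescaled(self, row_factor: float, col_factor: float) -> "Calibration":
        """Calibration after resizing the raster by (row_factor, col_factor).

        A raster resized to half its width doubles the time spanned by each
        remaining column.
        """
        return Calibration(
            time_per_px=self.time_per_px / col_factor,
            vel_per_px=self.vel_per_px / row_factor,
            zero_line_row=self.zero_line_row * row_factor,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(
            time_per_px=float(d["time_per_px"]),
            vel_per_px=float(d["vel_per_px"]),
            zero_line_row=float(d["zero_line_row"]),
        )
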