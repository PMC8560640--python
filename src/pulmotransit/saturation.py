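"""Signal-to-concentration conversion for first-pass perfusion.

MR blood-pool signal is not linear in gadolinium concentration: at the doses
used for perfusion imaging the signal saturates.  The package models the
relationship with a monotone forward map ``f`` from concentration c (mmol/l)
to normalized enhancement ``(S - S0)/S0``, where ``S0`` is the pre-contrast
baseline signal.  Because ``f`` is strictly increasing it is invertible, and
measured enhancement can be mapped back to concentration.

Two calibrations are provided: a one-parameter hyperbolic map (the default)
and a tabulated map for user-supplied monotone look-up tables.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator


class SaturationOverflowError(ValueError):
    """Enhancement outside the invertible range of the forward map."""


class HyperbolicSaturation(BaseEstimator):
    """Hyperbolic (Michaelis-Menten-like) saturation model.

    Forward map::

        f(c) = gain * c / (1 + c / c_sat)

    which is strictly increasing on c >= 0 with asymptote ``gain * c_sat``.
    The inverse is closed-form: ``c = e / (gain - e / c_sat)``.

    Parameters
    ----------
    s0 : float
        Baseline (pre-contrast) signal in arbitrary scanner units.
    c_sat : float
        Saturation concentration in mmol/l; larger values mean a more
        linear response over the first-pass range.
    gain : float
        Enhancement per mmol/l in the linear limit.
    """

    def __init__(self, s0: float = 100.0, c_sat: float = 8.0, gain: float = 1.0):
        self.s0 = s0
        self.c_sat = c_sat
        self.gain = gain

    def _validate(self) -> None:
        if self.s0 <= 0 or self.c_sat <= 0 or self.gain <= 0:
            raise ValueError("s0, c_sat and gain must all be positive")

    def forward(self, conc):
        """Concentration (mmol/l) -> normalized enhancement (S-S0)/S0."""
        self._validate()
        c = np.asarray(conc, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative")
        return self.gain * c / (1.0 + c / self.c_sat)

    def inverse(self, enhancement):
        """Normalized enhancement -> concentration (mmol/l).

        Negative enhancement (noise below baseline) is clipped to zero
        concentration.  Enhancement at or above the asymptote ``gain*c_sat``
        cannot be inverted and raises :class:`SaturationOverflowError`.
        """
        self._validate()
        e = np.clip(np.asarray(enhancement, dtype=float), 0.0, None)
        ceiling = self.gain * self.c_sat
        if np.any(e >= ceiling * (1.0 - 1e-9)):
            raise SaturationOverflowError(
                f"enhancement reaches the saturation asymptote ({ceiling:.3g}); "
                "signal cannot be inverted to concentration"
            )
        return e / (self.gain - e / self.c_sat)

    # transformer-style aliases so the calibration composes with pipelines
    def transform(self, conc):
        return self.forward(conc)

    def inverse_transform(self, enhancement):
        return self.inverse(enhancement)


class TabulatedSaturation(BaseEstimator):
    """Monotone look-up-table calibration.

    Accepts a user-supplied table of (concentration, enhancement) pairs and
    interpolates linearly in both directions.  The table must be strictly
    increasing in both columns.
    """

    def __init__(self, conc_grid=None, enh_grid=None, s0: float = 100.0):
        self.conc_grid = conc_grid
        self.enh_grid = enh_grid
        self.s0 = s0

    def _grids(self):
        c = np.asarray(self.conc_grid, dtype=float)
        e = np.asarray(self.enh_grid, dtype=float)
        if c.ndim != 1 or c.shape != e.shape or c.size < 2:
            raise ValueError("conc_grid and enh_grid must be 1-D of equal length >= 2")
        if np.any(np.diff(c) <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError("look-up table must be strictly increasing (monotone map)")
        return c, e

    def forward(self, conc):
        c_grid, e_grid = self._grids()
        c = np.asarray(conc, dtype=float)
        if np.any(c < c_grid[0]) or np.any(c > c_grid[-1]):
            raise ValueError("concentration outside tabulated range")
        return np.interp(c, c_grid, e_grid)

    def inverse(self, enhancement):
        c_grid, e_grid = self._grids()
        e = np.clip(np.asarray(enhancement, dtype=float), e_grid[0], None)
        if np.any(e > e_grid[-1]):
            raise SaturationOverflowError("enhancement above tabulated range")
        return np.interp(e, e_grid, c_grid)

    def transform(self, conc):
        return self.forward(conc)

    def inverse_transform(self, enhancement):
        return self.inverse(enhancement)
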