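"""Synthetic closed-form dendritic-current generator.

A C-infinity, bounded stand-in for the full axonal + synapto-dendritic
simulation chain, used to exercise the surrogate machinery at scale without
cluster-level compute.  It mimics the phenomenology of the simulated mean
current: a fast excitatory peak whose amplitude grows with field intensity
and excitatory fraction, an intensity-dependent secondary bump, a slow
NMDA-weighted component that redistributes early current into a late tail,
and inhibitory GABAa/GABAb components of opposite sign.  Every term couples
at most three of the six parameters, matching the physical observation that
the leading variance contributions come from single parameters and low-order
combinations.

This is a synthetic reference object, not output of the cable model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surrogate import ParamBounds, default_time_grid

__all__ = ["AnalyticDendriticCurrent"]


def _biexp(t: np.ndarray, tau_rise: float, tau_fall: float) -> np.ndarray:
    """Peak-normalized double exponential."""
    tmax = tau_rise * tau_fall / (tau_fall - tau_rise) * np.log(tau_fall / tau_rise)
    norm = np.exp(-tmax / tau_fall) - np.exp(-tmax / tau_rise)
    return (np.exp(-t / tau_fall) - np.exp(-t / tau_rise)) / norm


@dataclass
class AnalyticDendriticCurrent:
    """Closed-form I(t, xi) over the six surrogate parameters (nA).

    ``evaluate(X)`` maps parameter rows (theta deg, d|E| %/mm, |E| V/m,
    f_NMDA, f_GABAa, f_ex) to current time courses on ``t_grid`` (ms).
    """

    bounds: ParamBounds = field(default_factory=ParamBounds)
    t_grid: np.ndarray = field(default_factory=default_time_grid)
    amplitude_na: float = 2.0

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != len(self.bounds):
            raise ValueError(f"expected {len(self.bounds)} parameters per row")
        theta, grad, inten, f_nmda, f_gabaa, f_ex = X.T
        t = self.t_grid[None, :]

        # normalized inputs
        th = theta / 180.0                        # [0, 1]
        sg = grad / 20.0                          # [-1, 1]
        en = (inten - 100.0) / 300.0              # [0, 1]

        # recruitment grows smoothly with intensity; directional tuning
        # favors fields parallel/antiparallel to the somatodendritic axis
        recruit = 0.30 + 0.70 * en * (0.5 + 0.5 * en)
        ang = 0.55 + 0.45 * np.cos(np.pi * th) ** 2 + 0.12 * np.cos(np.pi * th)

        sh_fast = _biexp(t, 1.2, 7.0)
        sh_nmda = _biexp(t, 6.0, 45.0)
        sh_gabaa = _biexp(t, 1.5, 14.0)
        sh_gabab = _biexp(t, 8.0, 80.0)
        # intensity-dependent secondary bump (earlier and present at high |E|)
        t2 = (6.0 - 1.0 * en)[:, None]
        bump = np.exp(-0.5 * ((t - t2) / 3.0) ** 2)

        col = lambda a: a[:, None]  # noqa: E731

        i = (
            col(f_ex * recruit * ang) * sh_fast
            + 0.40 * col(recruit * ang) * bump * col(0.5 + 0.5 * en)
            + 0.08 * col(sg * recruit * f_ex) * sh_fast
            - 0.50 * col(f_nmda * f_ex * recruit) * (sh_fast - 0.6 * sh_nmda)
            + 0.25 * col(f_ex * recruit * en) * sh_nmda
            - 0.60 * col((1.0 - f_ex) * recruit * f_gabaa) * sh_gabaa
            - 0.78 * col((1.0 - f_ex) * recruit * (1.0 - f_gabaa)) * sh_gabab
            + 0.03 * col(ang * sg) * sh_nmda
        )
        return self.amplitude_na * i

    __call__ = evaluate
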