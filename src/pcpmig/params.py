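"""Generative motility parameters and per-condition presets.

The simulator models a migrating B lymphocyte as a biased persistent
random walk: at each frame the cell draws a new heading from a circular
(von Mises) distribution concentrated around a compromise between its
previous heading (persistence) and the direction of the chemokine
source (bias), then steps forward a gamma-distributed distance.

Presets encode the qualitative phenomenology of the four experimental
conditions studied in Dunn-chamber chemotaxis assays of MEC1 cells:

======================  ===========  ========  =====  =========
condition               speed mean   bias      A      arrested
                        (um/min)     (kappa)
======================  ===========  ========  =====  =========
control                 4.0          0.0       0.3    no
ccl19                   7.0          2.0       0.3    no
ccl19_ck1i              2.0          0.0       0.0    no
cytochalasin            0 (arrest)   0.0       0.3    yes
======================  ===========  ========  =====  =========

The speeds are simulator conventions consistent with cells 15-20 um in
diameter covering their own size in under 4 minutes; they are not
measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["MotilityParams", "condition_preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class MotilityParams:
    """Parameters of the biased persistent random walk for one condition.

    Attributes
    ----------
    speed_mean, speed_sd : float
        Mean and standard deviation of the per-step speed, um/min.
    persistence_kappa : float
        Concentration of the heading update toward the previous
        heading (>= 0; 0 = no persistence).
    bias_kappa : float
        Concentration of the heading update toward the chemokine
        source (>= 0; 0 = no chemotactic bias).
    polarity_amplitude : float
        Fractional modulation A of the membrane marker around the cell
        perimeter, 0 <= A < 1.  The marker intensity at perimeter angle
        phi is proportional to 1 + A*cos(phi - phi_peak).
    polarity_sign : int
        +1 for trailing-edge enrichment (VANGL2/ROR2-like), -1 for
        leading-edge enrichment (DVL3/beta-arrestin-like).
    arrested : bool
        If True, per-step displacement is zero and the polarity axis
        stays frozen at its last value (cytochalasin-like arrest).
    """

    speed_mean: float
    speed_sd: float
    persistence_kappa: float
    bias_kappa: float
    polarity_amplitude: float
    polarity_sign: int = 1
    arrested: bool = False

    def __post_init__(self) -> None:
        if self.speed_mean < 0:
            raise ValueError(f"speed_mean must be >= 0, got {self.speed_mean}")
        if self.speed_sd < 0:
            raise ValueError(f"speed_sd must be >= 0, got {self.speed_sd}")
        if self.persistence_kappa < 0:
            raise ValueError(
                f"persistence_kappa must be >= 0, got {self.persistence_kappa}"
            )
        if self.bias_kappa < 0:
            raise ValueError(f"bias_kappa must be >= 0, got {self.bias_kappa}")
        if not 0.0 <= self.polarity_amplitude < 1.0:
            raise ValueError(
                "polarity_amplitude must satisfy 0 <= A < 1 "
                f"(marker intensity stays non-negative), got {self.polarity_amplitude}"
            )
        if self.polarity_sign not in (-1, 1):
            raise ValueError(f"polarity_sign must be +1 or -1, got {self.polarity_sign}")


_CONTROL = MotilityParams(
    speed_mean=4.0,
    speed_sd=2.0,
    persistence_kappa=2.0,
    bias_kappa=0.0,
    polarity_amplitude=0.3,
)

_PRESETS = {
    # no gradient: moderate speed, persistent but undirected walk
    "control": _CONTROL,
    # chemokine gradient: faster, strongly biased toward the source
    "ccl19": replace(_CONTROL, speed_mean=7.0, bias_kappa=2.0),
    # gradient + CK1 inhibitor: slow, unbiased, marker asymmetry lost
    "ccl19_ck1i": replace(
        _CONTROL, speed_mean=2.0, speed_sd=1.0, bias_kappa=0.0, polarity_amplitude=0.0
    ),
    # actin depolymerisation: motile arrest, marker asymmetry retained
    "cytochalasin": replace(_CONTROL, arrested=True),
}

PRESET_NAMES = tuple(_PRESETS)


def condition_preset(name: str) -> MotilityParams:
    """Return the motility parameters for a named experimental condition.

    Raises
    ------
    ValueError
        If ``name`` is not one of ``PRESET_NAMES``.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        valid = ", ".join(PRESET_NAMES)
        raise ValueError(f"unknown condition {name!r}; valid names: {valid}") from None
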