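"""Ionic channel specifications.

A channel couples a gating scheme to a conductance density and reversal
potential on one compartment.  Densities are stored in the parameter files in
S/cm² (the unit the model literature prints) and converted to absolute nS when
a cell is compiled for simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gating import GateSpec


@dataclass(frozen=True)
class NapKinetics:
    """Kinetic scale parameters of the persistent-Na activation gate.

    ``a_on`` and ``a_off`` (ms) are the characteristic time scales of the
    activation (on) and deactivation (off) rate expressions: the forward rate
    is proportional to ``1/a_on`` and the backward rate to ``1/a_off``.  The
    anesthetic condition changes (a_on, a_off) from (0.75, 0.005) to
    (1.5, 0.05).  Because the off-time grows tenfold while the on-time only
    doubles, the activation midpoint shifts toward hyperpolarized potentials
    and the gate relaxes more slowly near threshold, so the persistent current
    engages earlier during a depolarizing approach and the firing threshold
    drops.
    """

    a_on: float
    a_off: float

    def __post_init__(self) -> None:
        if self.a_on <= 0 or self.a_off <= 0:
            raise ValueError(
                f"Nap kinetic scales must be positive, got ({self.a_on}, {self.a_off})"
            )

    @property
    def on_rate_scale(self) -> float:
        """Forward-rate multiplier, 1/ms (reciprocal of the on-time scale)."""
        return 1.0 / self.a_on

    @property
    def off_rate_scale(self) -> float:
        """Backward-rate multiplier, 1/ms (reciprocal of the off-time scale)."""
        return 1.0 / self.a_off


@dataclass
class ChannelSpec:
    """One conductance on one compartment.

    Parameters
    ----------
    name : str
        Channel identifier (``na_t``, ``na_p``, ``kv``, ``ka``, ``kir``,
        ``ca_hva``, ``kca``, ``leak``, ``gaba_leak``).
    compartment : str
        Name of the hosting compartment.
    density_S_per_cm2 : float
        Maximal conductance density; non-negative.
    erev_mV : float
        Reversal potential.  For the ohmic leak this is adjusted at build time
        to place the resting potential at the target value.
    gates : list of GateSpec
        Voltage-dependent gating variables (empty for leaks).
    ca_gate : dict or None
        Calcium-dependent gate (``{"kd_mM": ..., "tau_ms": ..., "exponent": n}``),
        used by the Ca-activated K channel.
    is_ca_source : bool
        Whether this channel's current feeds the submembrane Ca pool.
    t_orig_C : float
        Reference temperature of the encoded kinetics.
    """

    name: str
    compartment: str
    density_S_per_cm2: float
    erev_mV: float
    gates: list[GateSpec] = field(default_factory=list)
    ca_gate: dict | None = None
    is_ca_source: bool = False
    t_orig_C: float = 37.0

    def __post_init__(self) -> None:
        if self.density_S_per_cm2 < 0:
            raise ValueError(
                f"channel {self.name!r}: density must be >= 0, "
                f"got {self.density_S_per_cm2}"
            )


def nap_gate(kinetics: NapKinetics, shape: dict, exponent: int = 1) -> GateSpec:
    """Build the persistent-Na activation gate from its kinetic time scales.

    ``shape`` holds the voltage dependence of the exponential forward and
    backward rates (``v0``, ``ka``, ``kb``) and their magnitudes (``a_mag``,
    ``b_mag``):  ``alpha = (a_mag/a_on)·exp((V−v0)/ka)`` and
    ``beta = (b_mag/a_off)·exp(−(V−v0)/kb)``, giving a Boltzmann steady state
    whose midpoint moves with ``ln(a_on/a_off)``.
    """
    return GateSpec(
        name="m",
        form="rates_exp",
        params={
            "a_scale": shape["a_mag"] * kinetics.on_rate_scale,
            "b_scale": shape["b_mag"] * kinetics.off_rate_scale,
            "v0": shape["v0"],
            "ka": shape["ka"],
            "kb": shape["kb"],
        },
        exponent=exponent,
        q10_class="gating",
    )
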