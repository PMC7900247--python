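"""Q10 temperature scaling of kinetic rates and conductances.

Every rate or permeability in the model is defined at a reference temperature
``t_orig`` recorded in the parameter files and rescaled to the simulation
temperature with the standard exponential Q10 law.  Process classes follow the
usual biophysical convention: channel gating rates scale steeply (Q10 = 3),
ligand-gated receptor transitions less so (2.4), open-channel permeation
weakly (1.5), and diffusion-limited processes weakest (1.3).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Default Q10 per process class. Rates in the "gating"/"receptor"/"ca_pump"
#: classes multiply by the factor; conductances in "permeation" multiply by it;
#: diffusion time constants divide by it.
Q10_CLASSES = {
    "gating": 3.0,
    "receptor": 2.4,
    "permeation": 1.5,
    "diffusion": 1.3,
    "ca_pump": 3.0,
    # intracellular Ca diffusion: cell-type dependent (granule vs Golgi)
    "ca_diffusion_grc": 1.3,
    "ca_diffusion_goc": 1.7,
}

DEFAULT_TEMP_C = 30.0


def q10_factor(q10: float, t_orig: float, t_sim: float) -> float:
    """Multiplicative temperature-correction factor ``q10**((t_sim-t_orig)/10)``.

    Applied to kinetic rates (gating, receptor classes) or maximal
    conductances (permeation class).  Equals 1 when the two temperatures
    coincide and is strictly positive for any positive ``q10``.

    Parameters
    ----------
    q10 : float
        Fold change per 10 °C; must be positive.
    t_orig, t_sim : float
        Reference and target temperatures, °C.
    """
    if q10 <= 0:
        raise ValueError(f"q10 must be positive, got {q10}")
    return float(q10) ** ((float(t_sim) - float(t_orig)) / 10.0)


@dataclass(frozen=True)
class TemperatureCorrection:
    """Temperature context for compiling a model.

    ``factor(process)`` returns the rate multiplier for a named process class
    when going from the class's reference temperature to ``t_sim``.
    """

    t_sim: float = DEFAULT_TEMP_C

    def factor(self, process: str, t_orig: float, q10: float | None = None) -> float:
        q = Q10_CLASSES[process] if q10 is None else q10
        return q10_factor(q, t_orig, self.t_sim)
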