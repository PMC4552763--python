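"""hemoflow: particle-based blood flow with open inflow/outflow boundaries.

A dissipative-particle-dynamics (DPD) plasma fluid, a coarse-grained
triangulated-membrane red-blood-cell model, and an open-boundary framework
(generating region + copy-border duplication inflow, adaptive
probabilistic-membrane outflow) for simulating suspensions in tubes and
microvascular bifurcations.
"""

from . import core, dpd, forces, geometry, io, membrane, obc, observables

__version__ = "0.1.0"

__all__ = ["core", "dpd", "forces", "geometry", "io", "membrane", "obc",
           "observables", "scenarios", "__version__"]


def __getattr__(name):
    if name == "scenarios":
        from . import scenarios
        return scenarios
    raise AttributeError(name)
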