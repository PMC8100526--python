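"""Bundled occupancy datasets for the Mac-1/GPIbα interface.

Two tables of interface hydrogen-bond occupancies (survival ratios), in the
reduced residue-pair dialect, as published for the docked Mac-1 I-domain /
GPIbα complex:

* ``model_occupancies`` — occupancies of the 14 interface H-bond residue
  pairs in three docking models of the unloaded complex (Model I: raw dock;
  Models II/III: after mechanical load–release refinement).  Zero means the
  bond was not observed in that model.
* ``force_panel`` — occupancies of the 11 strongest interface H-bonds under
  constant tensile forces of 0, 25, 50 and 75 pN (mean over three
  force-clamp runs).

First column: Mac-1 residue; second column: GPIbα residue (author
numbering).
"""

from importlib import resources

from ..interactions import OccupancyTable

__all__ = ["load_model_occupancies", "load_force_panel"]


def _load(name: str) -> OccupancyTable:
    ref = resources.files(__package__) / name
    with resources.as_file(ref) as path:
        return OccupancyTable.read_reduced(path)


def load_model_occupancies() -> OccupancyTable:
    """Interface H-bond occupancies of the three unloaded docking models
    (conditions ``Model_I``, ``Model_II``, ``Model_III``)."""
    return _load("model_occupancies.tsv")


def load_force_panel() -> OccupancyTable:
    """Interface H-bond occupancies under 0/25/50/75 pN tensile force
    (conditions ``0``, ``25``, ``50``, ``75``)."""
    return _load("force_panel.tsv")
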