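"""Published summary figures for the Phanerozoic marine genus compendium.

The compendium of mode-of-life assignments for fossil marine animal genera
(compiled from the synoptic stratigraphic-range sources and ecospace-cube
codings) spans nine phyla.  These constants record its published
composition; they are inputs for arithmetic cross-checks, not quantities
this package computes.
"""

from __future__ import annotations

__all__ = ["PHYLUM_GENUS_COUNTS", "TOTAL_GENERA", "GENUS_STAGE_COMBINATIONS"]

#: Genus counts per phylum in the published compendium.
PHYLUM_GENUS_COUNTS: dict[str, int] = {
    "Arthropoda": 1344,
    "Brachiopoda": 3956,
    "Bryozoa": 379,
    "Chordata": 1463,
    "Cnidaria": 1790,
    "Echinodermata": 2003,
    "Hemichordata": 253,
    "Mollusca": 6551,
    "Porifera": 882,
}

#: Published total number of genera with stage-resolved ranges and a mode.
TOTAL_GENERA: int = 18_621

#: Published number of genus-by-stage occurrence rows after range-through
#: expansion of the full compendium.
GENUS_STAGE_COMBINATIONS: int = 161_947
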