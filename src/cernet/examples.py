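"""Worked example: the published aged-rat ceRNA network around ENSRNOT00000029245.

The reported network places the up-regulated lncRNA ENSRNOT00000029245
upstream of two miRNA hubs: miR484x, through which it up-regulates 23 mRNAs,
and rno-miR-653-5p, through which it regulates 14 mRNAs; the mRNA Il6r is
additionally reached through BOTH axes (it appears in neither axis-exclusive
list).  These edge lists are carried here verbatim so the network-assembly
and export code can be exercised against published topology.
"""

from __future__ import annotations

import networkx as nx

from .cerna import network_from_axes

LNCRNA = "ENSRNOT00000029245"
MIR_484X = "miR484x"
MIR_653 = "rno-miR-653-5p"

# mRNAs up-regulated exclusively through the miR484x axis (23)
MIR_484X_MRNAS = (
    "Tspan18", "Mtss1", "Szrd1", "Pik3cg", "NEWGENE_619861", "Fgf1", "Btrc",
    "B2m", "Ggta1", "kdm4a", "Fxyd7", "Naf1", "Vps9d1", "Ppm1l", "Bcl2l1",
    "RGD1560281", "Scamp1", "Sele", "Nrcam", "Hsp90b1", "Cmpk1", "Fam20b",
    "Hiatl3",
)

# mRNAs regulated exclusively through the rno-miR-653-5p axis (14)
MIR_653_MRNAS = (
    "Sorcs3", "LOC100910882", "Morf4l2", "Ptprd", "Hmgcs1", "Lox", "Gpm6a",
    "Trim32", "Tnfrsf11b", "Phf14", "Ncapg2", "Cyyr1", "Reep3", "Nus1",
)

# reached through both axes
SHARED_MRNA = "Il6r"


def aed_network() -> nx.Graph:
    """Build the published network: all lncRNA/mRNA nodes up, miRNAs down."""
    axes = {
        MIR_484X: (*MIR_484X_MRNAS, SHARED_MRNA),
        MIR_653: (*MIR_653_MRNAS, SHARED_MRNA),
    }
    return network_from_axes(LNCRNA, axes)
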