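"""Reference sequences used by the residue-mapping and bookkeeping analyses.

The pore-region fragments below carry the author residue numbering used in
the structural analysis: Shaker Kv numbering (F425 / Y445 / T449) and the
Kv1.2-based paddle-chimera numbering (Q353 / D359 / Y373 / D375 / V377).
In the pore region the two sequences align without gaps at a constant
offset of 72.
"""

from __future__ import annotations

#: Charybdotoxin, 37 residues.  The N-terminal pyroglutamate is stored as E.
#: Cysteines at 7, 13, 17, 28, 33, 35 pair into the three disulfides
#: 7-28, 13-33, 17-35; Lys27 is the conserved pore-plugging lysine and
#: Met29 the selenomethionine marker site.
CTX_SEQUENCE = "EFTNVSCTTSKECWSVCQRLHNTSRGKCMNKKCRCYS"
CTX_FIRST_RESIDUE = 1
CTX_DISULFIDES = [(7, 28), (13, 33), (17, 35)]
CTX_CONSERVED_LYSINE = 27

#: Agitoxin-2, 38 residues; Gly10 and Lys27 are the mutant-cycle landmarks.
AGTX2_SEQUENCE = "GVPINVSCTGSPQCIKPCKDAGMRFGKCMNRKCHCTPK"
AGTX2_FIRST_RESIDUE = 1

#: Shaker Kv pore region (S5-pore-S6), author numbering starting at 418.
SHAKER_PORE = "EAGSENSFFKSIPDAFWWAVVTMTTVGYGDMTPVGVWGKIVGSLCAIAGVLTIALPVPVIVSNFNYFYHRET"
SHAKER_PORE_FIRST = 418

#: Paddle-chimera (Kv1.2 pore) region, author numbering starting at 346.
CHIMERA_PORE = "EADERDSQFPSIPDAFWWAVVSMTTVGYGDMVPTTIGGKIVGSLCAIAGVLTIALPVPVIVSNFNYFYHRET"
CHIMERA_PORE_FIRST = 346


def cysteine_positions(sequence: str, first_residue: int = 1) -> list[int]:
    return [first_residue + i for i, aa in enumerate(sequence) if aa == "C"]


def disulfide_count(sequence: str) -> int:
    """Number of disulfide bonds assuming all cysteines are paired."""
    n_cys = sequence.count("C")
    if n_cys % 2:
        raise ValueError(f"odd cysteine count {n_cys}: cannot fully pair")
    return n_cys // 2
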