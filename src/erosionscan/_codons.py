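"""Genetic-code bookkeeping shared by the codon model, simulator and
fourfold-degenerate-site extraction.

All structures are derived from NCBI translation tables (via Biopython's
``Bio.Data.CodonTable``), never hard-coded, so any table id works. Codons
are indexed over the sense codons of the chosen table in lexicographic
(A<C<G<T) order; stop codons are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

#: unordered purine/pyrimidine pairs whose interchange is a transition
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


@dataclass(frozen=True)
class CodonCode:
    """Sense-codon index and single-nucleotide-step structure for one
    genetic-code table."""

    table_id: int
    codons: tuple[str, ...]                 # sense codons, lexicographic
    stops: frozenset[str]
    aa: tuple[str, ...]                     # amino acid per sense codon
    index: dict[str, int] = field(repr=False)
    # arrays over single-nucleotide-difference sense-codon pairs (directed)
    pair_i: np.ndarray = field(repr=False)
    pair_j: np.ndarray = field(repr=False)
    pair_pos: np.ndarray = field(repr=False)      # codon position 0/1/2
    pair_target: np.ndarray = field(repr=False)   # target nucleotide index
    pair_ts: np.ndarray = field(repr=False)       # transition flag
    pair_syn: np.ndarray = field(repr=False)      # synonymous flag
    codon_nuc: np.ndarray = field(repr=False)     # (n, 3) nucleotide indices
    fourfold_prefixes: frozenset[str] = frozenset()

    @property
    def n(self) -> int:
        return len(self.codons)

    def translate(self, codon: str) -> str | None:
        """Amino acid for a sense codon, ``*`` for stop, None if ambiguous."""
        codon = codon.upper().replace("U", "T")
        if codon in self.stops:
            return "*"
        i = self.index.get(codon)
        return None if i is None else self.aa[i]


@lru_cache(maxsize=None)
def get_code(table_id: int = 1) -> CodonCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = frozenset(table.stop_codons)
    codons = tuple(
        "".join(c) for c in product(NUCS, repeat=3) if "".join(c) not in stops
    )
    index = {c: i for i, c in enumerate(codons)}
    aa = tuple(table.forward_table[c] for c in codons)

    pi, pj, pos, tgt, ts, syn = [], [], [], [], [], []
    for i, x in enumerate(codons):
        for p in range(3):
            for n in NUCS:
                if n == x[p]:
                    continue
                y = x[:p] + n + x[p + 1:]
                j = index.get(y)
                if j is None:  # stop codon target: disallowed
                    continue
                pi.append(i)
                pj.append(j)
                pos.append(p)
                tgt.append(NUC_INDEX[n])
                ts.append(is_transition(x[p], n))
                syn.append(aa[i] == aa[j])

    fourfold = frozenset(
        a + b
        for a in NUCS
        for b in NUCS
        if all(a + b + c not in stops for c in NUCS)
        and len({table.forward_table[a + b + c] for c in NUCS}) == 1
    )
    return CodonCode(
        table_id=table_id,
        codons=codons,
        stops=stops,
        aa=aa,
        index=index,
        pair_i=np.asarray(pi, dtype=np.intp),
        pair_j=np.asarray(pj, dtype=np.intp),
        pair_pos=np.asarray(pos, dtype=np.intp),
        pair_target=np.asarray(tgt, dtype=np.intp),
        pair_ts=np.asarray(ts, dtype=bool),
        pair_syn=np.asarray(syn, dtype=bool),
        codon_nuc=np.array(
            [[NUC_INDEX[ch] for ch in codon] for codon in codons],
            dtype=np.intp,
        ),
        fourfold_prefixes=fourfold,
    )
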