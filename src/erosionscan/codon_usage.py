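"""Codon-usage-bias descriptors: positional GC content, Wright's effective
number of codons (ENC), and the neutrality regression.

ENC measures how evenly a CDS spreads its codon usage over synonymous
alternatives: 20 means one codon per amino acid (maximal bias), 61 means
uniform synonymous usage. The neutrality plot regresses GC12 =
(GC1 + GC2) / 2 on GC3 across CDSs: a slope near 1 indicates mutation
pressure dominating all three positions, a flat slope indicates selection
holding first/second positions while third positions drift. The ENC~GC3
plot compares observed ENC with Wright's no-selection expectation
ENC_exp(s) = 2 + s + 29 / (s^2 + (1-s)^2).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from ._codons import get_code

__all__ = [
    "CodonUsageProfile",
    "gc_by_position",
    "effective_number_of_codons",
    "neutrality_regression",
    "wright_expected_enc",
    "profile_cds",
]

_GC = set("GC")
_UNAMBIG = set("ACGT")


def _strip_terminal_stop(seq: str, table_id: int) -> str:
    code = get_code(table_id)
    if len(seq) >= 3 and seq[-3:] in code.stops:
        return seq[:-3]
    return seq


def gc_by_position(cds: str, table_id: int = 1) -> tuple[float, float, float]:
    """GC fraction at each codon position of a CDS.

    Ambiguous bases are excluded from numerator and denominator; a terminal
    stop codon is stripped first. Raises on length not divisible by 3 or an
    empty sequence after stripping.
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    seq = _strip_terminal_stop(seq, table_id)
    if not seq:
        raise ValueError("empty CDS after stripping the terminal stop")
    out = []
    for pos in range(3):
        bases = [seq[i] for i in range(pos, len(seq), 3)
                 if seq[i] in _UNAMBIG]
        if not bases:
            out.append(float("nan"))
        else:
            out.append(sum(b in _GC for b in bases) / len(bases))
    return tuple(out)


def _synonymous_families(table_id: int) -> dict[str, list[str]]:
    """Amino acid -> list of sense codons, from the code table."""
    code = get_code(table_id)
    fams: dict[str, list[str]] = defaultdict(list)
    for codon, aa in zip(code.codons, code.aa):
        fams[aa].append(codon)
    return dict(fams)


def effective_number_of_codons(codon_counts: dict[str, int],
                               table_id: int = 1) -> float:
    """Wright's ENC from per-codon counts.

    Per family, the homozygosity estimate is
    F-hat = (n * sum p-hat^2 - 1) / (n - 1); families observed fewer than
    twice are imputed with the mean F-hat of their degeneracy class
    (missing threefold class: mean of the two- and fourfold means). The
    result is clamped to [20, 61]. Raises when no family is estimable.
    """
    fams = _synonymous_families(table_id)
    by_size: dict[int, list[float]] = defaultdict(list)
    n_families: dict[int, int] = defaultdict(int)
    n_single = 0
    for aa, codons in fams.items():
        size = len(codons)
        if size == 1:
            n_single += 1
            continue
        n_families[size] += 1
        n = sum(codon_counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        p = np.array([codon_counts.get(c, 0) / n for c in codons])
        f_hat = (n * float(np.sum(p ** 2)) - 1.0) / (n - 1.0)
        by_size[size].append(f_hat)

    if not any(by_size.values()):
        raise ValueError("no synonymous family observed at least twice")

    means: dict[int, float] = {}
    for size in n_families:
        if by_size.get(size):
            means[size] = float(np.mean(by_size[size]))
    # missing threefold class: mean of the *estimated* two/fourfold means
    if 3 in n_families and 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2.0
    for size in n_families:
        if size not in means:  # fall back to the uniform-usage value
            means[size] = 1.0 / size

    enc = float(n_single)
    for size, count in n_families.items():
        mean_f = max(means[size], 1e-9)
        enc += count / mean_f
    return float(np.clip(enc, 20.0, 61.0))


def wright_expected_enc(gc3: float) -> float:
    """Wright's no-selection ENC expectation at third-position GC
    content s: 2 + s + 29 / (s^2 + (1-s)^2)."""
    s = gc3
    return 2.0 + s + 29.0 / (s ** 2 + (1.0 - s) ** 2)


@dataclass
class CodonUsageProfile:
    """Per-CDS usage descriptors."""

    gene: str
    gc1: float
    gc2: float
    gc3: float
    enc: float
    enc_expected: float
    codon_counts: dict[str, int]

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


def profile_cds(gene: str, cds: str, table_id: int = 1) -> CodonUsageProfile:
    """Build the full usage profile of one CDS."""
    seq = _strip_terminal_stop(cds.upper().replace("U", "T"), table_id)
    gc1, gc2, gc3 = gc_by_position(cds, table_id)
    counts = Counter(
        seq[i: i + 3]
        for i in range(0, len(seq), 3)
        if not set(seq[i: i + 3]) - _UNAMBIG
    )
    return CodonUsageProfile(
        gene=gene,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        enc=effective_number_of_codons(counts, table_id),
        enc_expected=wright_expected_enc(gc3),
        codon_counts=dict(counts),
    )


@dataclass
class NeutralityFit:
    slope: float | None
    intercept: float | None
    r: float | None
    gc3: np.ndarray
    gc12: np.ndarray
    enc_expected: np.ndarray


def neutrality_regression(profiles: list[CodonUsageProfile]) -> NeutralityFit:
    """OLS of GC12 on GC3 across the CDSs of one species.

    Also evaluates Wright's expected-ENC curve at each CDS's GC3 for the
    ENC~GC3 plot. With fewer than 3 CDSs or zero GC3 variance the slope is
    undefined and reported as None.
    """
    gc3 = np.array([p.gc3 for p in profiles])
    gc12 = np.array([p.gc12 for p in profiles])
    enc_exp = np.array([wright_expected_enc(s) for s in gc3])
    if len(profiles) < 3 or np.isclose(np.var(gc3), 0.0):
        return NeutralityFit(None, None, None, gc3, gc12, enc_exp)
    slope, intercept = np.polyfit(gc3, gc12, 1)
    r = float(np.corrcoef(gc3, gc12)[0, 1])
    return NeutralityFit(float(slope), float(intercept), r, gc3, gc12,
                         enc_exp)
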