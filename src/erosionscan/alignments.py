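"""Codon alignments: gap-aware aligned coding sequences, FASTA I/O,
validation, and fourfold-degenerate-site extraction.

A fourfold-degenerate site is a third codon position at which any of the
four nucleotides encodes the same amino acid. Such sites evolve nearly
neutrally and are the standard input for divergence dating. Extraction here
is strict: a third position is kept only when every species has a complete,
unambiguous codon in that column, all species share the identical first two
positions, and that shared dinucleotide prefix is a fourfold family under
the genetic code in use (sixfold amino acids contribute only their fourfold
sub-family).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from ._codons import get_code

GAP_CHARS = set("-?.")
UNAMBIGUOUS = set("ACGT")

__all__ = ["CodonAlignment", "extract_fourfold_sites"]


@dataclass
class CodonAlignment:
    """Aligned coding sequences, one per species.

    Invariants (see :meth:`validate`): equal lengths, length divisible by 3,
    and no stop codon at any complete in-frame codon.
    """

    sequences: dict[str, str]
    table_id: int = 1

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, species: str, site: int) -> str:
        """Codon of `species` at 0-based codon column `site`."""
        return self.sequences[species][3 * site: 3 * site + 3]

    def validate(self) -> list[str]:
        report: list[str] = []
        if not self.sequences:
            report.append("empty alignment")
            return report
        lengths = {sp: len(s) for sp, s in self.sequences.items()}
        if len(set(lengths.values())) != 1:
            report.append(f"unequal sequence lengths: {lengths}")
            return report
        if self.length % 3 != 0:
            report.append(f"alignment length {self.length} not divisible by 3")
            return report
        code = get_code(self.table_id)
        for sp, seq in self.sequences.items():
            seq = seq.upper()
            for i in range(0, len(seq), 3):
                cod = seq[i: i + 3]
                if cod in code.stops:
                    report.append(
                        f"in-frame stop codon {cod} in {sp} at codon {i // 3}"
                    )
        return report

    @classmethod
    def from_fasta(cls, path, table_id: int = 1) -> "CodonAlignment":
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(seqs, table_id=table_id)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sp, seq in self.sequences.items():
                fh.write(f">{sp}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i: i + 70] + "\n")


@dataclass
class FourfoldSites:
    """Third-position columns retained by :func:`extract_fourfold_sites`."""

    sequences: dict[str, str]
    #: 0-based alignment columns of the retained third positions, increasing
    columns: list[int] = field(default_factory=list)


def extract_fourfold_sites(aln: CodonAlignment) -> FourfoldSites:
    """Extract fourfold-degenerate third-position sites from an alignment.

    Returns the per-species nucleotide strings over retained columns and the
    0-based alignment-column indices, strictly increasing. Raises
    ``ValueError`` on an empty alignment or one whose length is not a
    multiple of 3.
    """
    if not aln.sequences:
        raise ValueError("empty alignment")
    if aln.length % 3 != 0:
        raise ValueError(
            f"alignment length {aln.length} is not divisible by 3"
        )
    code = get_code(aln.table_id)
    species = aln.species
    seqs = {sp: aln.sequences[sp].upper() for sp in species}

    columns: list[int] = []
    kept = {sp: [] for sp in species}
    for site in range(aln.n_codons):
        codons = [seqs[sp][3 * site: 3 * site + 3] for sp in species]
        if any(set(c) - UNAMBIGUOUS for c in codons):
            continue  # gap or ambiguity in some species
        prefixes = {c[:2] for c in codons}
        if len(prefixes) != 1:
            continue  # first two codon positions differ between species
        if next(iter(prefixes)) not in code.fourfold_prefixes:
            continue
        columns.append(3 * site + 2)
        for sp, c in zip(species, codons):
            kept[sp].append(c[2])
    return FourfoldSites(
        sequences={sp: "".join(chars) for sp, chars in kept.items()},
        columns=columns,
    )
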