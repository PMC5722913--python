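"""Gene and operon annotation containers.

Coordinates are 1-based and inclusive throughout (GFF convention); a gene of
length ``l`` satisfies ``end - start + 1 == l``. Genes belong to operons;
``operon_position`` is the 0-based index in transcription order, so the
promoter-proximal gene of every operon has position 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene."""

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    operon_id: str
    operon_position: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.end < self.start:
            raise DataError(f"gene {self.gene_id}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware 5' end)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end coordinate (strand-aware 3' end)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class SyntheticGenome:
    """A gene/operon annotation with a genome length.

    Operons map operon id -> gene ids in transcription order. Despite the
    name this container also backs annotations read from GFF3/TSV files.
    """

    genes: list[GeneRecord]
    genome_length: int
    operons: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.operons:
            self.operons = self._operons_from_genes()
        self.validate()

    def _operons_from_genes(self) -> dict[str, list[str]]:
        grouped: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            grouped.setdefault(g.operon_id, []).append(g)
        return {
            op: [g.gene_id for g in sorted(members, key=lambda g: g.operon_position)]
            for op, members in grouped.items()
        }

    def validate(self) -> None:
        seen: dict[str, GeneRecord] = {}
        for g in self.genes:
            if g.gene_id in seen:
                raise DataError(f"duplicate gene id {g.gene_id}")
            seen[g.gene_id] = g
            if g.start < 1 or g.end > self.genome_length:
                raise DataError(
                    f"gene {g.gene_id} [{g.start},{g.end}] outside genome [1,{self.genome_length}]"
                )
        for op, gene_ids in self.operons.items():
            members = [seen[gid] for gid in gene_ids]
            strands = {g.strand for g in members}
            if len(strands) != 1:
                raise DataError(f"operon {op}: genes on mixed strands")
            # coordinate order must follow transcription direction
            key = [g.start for g in members]
            expected = sorted(key, reverse=(members[0].strand == "-"))
            if key != expected:
                raise DataError(f"operon {op}: genes not ordered in transcription direction")

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def promoter_distance(self, gene_id: str, to: str = "3prime") -> int:
        """Distance in nt from the operon promoter to a gene's 5' or 3' end.

        The operon promoter sits at the transcription start of the operon's
        first gene; intergenic gaps inside the operon are included.
        """
        g = self.gene(gene_id)
        first = self.gene(self.operons[g.operon_id][0])
        anchor = g.tes if to == "3prime" else g.tss
        return abs(anchor - first.tss) + 1
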