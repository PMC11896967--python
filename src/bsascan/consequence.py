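"""Coding-consequence annotation for candidate variants.

Applies an indel/substitution to a gene model's spliced CDS, translates with
the standard nuclear code, and reports frameshift status, premature-stop
position, and original vs mutant protein lengths (stop codon excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

from Bio.Seq import Seq

from .variants import GeneModel, VariantSite

EFFECT_FRAMESHIFT = "frameshift"
EFFECT_INFRAME = "inframe_indel"
EFFECT_SUBSTITUTION = "substitution"
EFFECT_NONCODING = "noncoding"


@dataclass(frozen=True)
class CodingConsequence:
    effect: str
    original_protein_len: int
    mutant_protein_len: int
    stop_found: bool
    stop_codon_index: int | None  # 1-based codon number of the first stop, mutant frame
    starts_with_start_codon: bool = True


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    protein_len: int
    stop_found: bool
    stop_codon_index: int | None
    starts_with_start_codon: bool


def extract_cds(model: GeneModel, genome: Mapping[str, str]) -> str:
    """Spliced coding-strand CDS sequence of a gene model.

    ``genome`` maps chromosome name to sequence (a dict or a pyfaidx.Fasta —
    anything whose ``[chrom]`` yields a sliceable, str()-able sequence).
    """
    seq = str(genome[model.chrom][:])
    parts = [seq[s - 1 : e] for s, e in model.cds_intervals]
    spliced = "".join(parts).upper()
    if model.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    return spliced


def _spliced_offset(model: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the genomic-orientation splice."""
    offset = 0
    for start, end in model.cds_intervals:
        if start <= pos <= end:
            return offset + (pos - start)
        offset += end - start + 1
    raise ValueError(f"position {pos} not inside any CDS interval of {model.gene_id}")


def apply_variant_to_cds(
    model: GeneModel, cds_sequence: str, variant: VariantSite
) -> str:
    """Apply a VCF-anchored variant to a spliced coding-strand CDS.

    ``cds_sequence`` must be the coding-strand spliced CDS of ``model`` (as
    from :func:`extract_cds`). The variant's ref allele must match the
    reference at its anchor (strand-aware); a mismatch is a hard error since it
    almost always indicates a coordinate bug. The entire ref allele must lie
    within a single CDS interval.
    """
    if not model.contains_cds(variant.pos):
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} outside CDS of {model.gene_id}"
        )
    # work in genomic orientation, flip at the end for minus-strand genes
    genomic = (
        str(Seq(cds_sequence).reverse_complement()) if model.strand == "-" else cds_sequence
    )
    off = _spliced_offset(model, variant.pos)
    ref = variant.ref.upper()
    end_pos = variant.pos + len(ref) - 1
    if not model.contains_cds(end_pos) or _spliced_offset(model, end_pos) != off + len(ref) - 1:
        raise ValueError(
            f"ref allele of {variant.chrom}:{variant.pos} spans a CDS boundary"
        )
    observed = genomic[off : off + len(ref)]
    if observed != ref:
        raise ValueError(
            f"ref mismatch at {variant.chrom}:{variant.pos}: "
            f"variant says {ref!r}, reference has {observed!r}"
        )
    mutant = genomic[:off] + variant.alt.upper() + genomic[off + len(ref) :]
    if model.strand == "-":
        mutant = str(Seq(mutant).reverse_complement())
    return mutant


def translate_and_truncate(coding_sequence: str) -> TranslationResult:
    """Translate a coding sequence with the standard nuclear code, to first stop.

    Protein length counts residues before the first stop codon; with no stop,
    ``stop_found`` is False and the length is ``len(seq) // 3``. A non-ATG
    start is flagged (warning), not an error.
    """
    seq = coding_sequence.upper()
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"non-ACGT characters in coding sequence: {bad}")
    starts_with_start = seq.startswith("ATG")
    if not starts_with_start:
        warnings.warn("coding sequence does not start with ATG", stacklevel=2)
    n_codons = len(seq) // 3
    protein = str(Seq(seq[: n_codons * 3]).translate())
    stop_idx = protein.find("*")
    if stop_idx == -1:
        return TranslationResult(protein, n_codons, False, None, starts_with_start)
    return TranslationResult(protein[:stop_idx], stop_idx, True, stop_idx + 1, starts_with_start)


def annotate_consequence(
    model: GeneModel,
    genome: Mapping[str, str],
    variant: VariantSite,
) -> CodingConsequence:
    """Full consequence call for one variant against one gene model.

    Variants outside every CDS interval are ``noncoding``. Within the CDS,
    indels whose length change is not a multiple of 3 are ``frameshift``;
    other length changes are ``inframe_indel``; equal-length changes are
    ``substitution``. Protein lengths are residues before the first stop.
    """
    if not model.contains_cds(variant.pos):
        return CodingConsequence(
            effect=EFFECT_NONCODING,
            original_protein_len=0,
            mutant_protein_len=0,
            stop_found=False,
            stop_codon_index=None,
        )
    cds = extract_cds(model, genome)
    original = translate_and_truncate(cds)
    mutant_seq = apply_variant_to_cds(model, cds, variant)
    mutant = translate_and_truncate(mutant_seq)
    shift = variant.indel_length % 3
    if variant.indel_length == 0:
        effect = EFFECT_SUBSTITUTION
    elif shift != 0:
        effect = EFFECT_FRAMESHIFT
    else:
        effect = EFFECT_INFRAME
    return CodingConsequence(
        effect=effect,
        original_protein_len=original.protein_len,
        mutant_protein_len=mutant.protein_len,
        stop_found=mutant.stop_found,
        stop_codon_index=mutant.stop_codon_index,
        starts_with_start_codon=original.starts_with_start_codon,
    )
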