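"""Allele naming against a local reference set.

A called allele receives the reference name when it is identical to a
reference sequence at full length; when it matches a reference with 100%
identity over their overlapping segment but differs in length (exact
substring/superstring containment), it receives the reference name with an
'a' suffix; anything else — including a single substitution anywhere — is
novel and receives the configured prefix with the next free number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genotyping import GenotypeCall

STATUS_KNOWN = "known"
STATUS_LENGTH_VARIANT = "known_length_variant"
STATUS_NOVEL = "novel"


@dataclass(frozen=True)
class AlleleName:
    sequence: str
    assigned_name: str
    status: str
    ambiguous_with: tuple[str, ...] = ()


def read_reference_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(name, sequence) pairs, preserving file order (order is the
    tie-break when several references match equally)."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def classify_allele(
    seq: str,
    reference: Sequence[tuple[str, str]],
    prefix: str = "Pado-UA*",
    next_number: int = 1,
) -> AlleleName:
    """Classify one sequence against the reference set.

    Full-length identity beats containment; within a priority class the
    first reference in file order wins and any equally-good later matches
    are reported as ambiguous.
    """
    names = [n for n, _ in reference]
    if len(set(names)) != len(names):
        raise ValueError("reference names must be unique")
    exact = [n for n, r in reference if r == seq]
    if exact:
        return AlleleName(seq, exact[0], STATUS_KNOWN, tuple(exact[1:]))
    contained = [
        n
        for n, r in reference
        if len(r) != len(seq) and (seq in r or r in seq)
    ]
    if contained:
        return AlleleName(
            seq, contained[0] + "a", STATUS_LENGTH_VARIANT, tuple(contained[1:])
        )
    return AlleleName(seq, f"{prefix}{next_number:03d}", STATUS_NOVEL)


def name_alleles(
    sequences: Iterable[str],
    reference: Sequence[tuple[str, str]] = (),
    prefix: str = "Pado-UA*",
    start_number: int = 1,
) -> dict[str, AlleleName]:
    """Name a set of sequences; novel numbering increments deterministically
    (sequences processed in sorted order) and never collides with a
    reference name."""
    taken = {n for n, _ in reference}
    number = start_number
    out: dict[str, AlleleName] = {}
    for seq in sorted(set(sequences)):
        while f"{prefix}{number:03d}" in taken:
            number += 1
        name = classify_allele(seq, reference, prefix, number)
        if name.status == STATUS_NOVEL:
            taken.add(name.assigned_name)
            number += 1
        out[seq] = name
    return out


def write_outputs(
    calls: Mapping[str, GenotypeCall],
    names: Mapping[str, AlleleName],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the sample x allele presence/absence matrix and the named
    allele FASTA, both deterministically ordered (samples, then allele
    names).  Amplicons without a good call contribute no presences."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    good = {s: c for s, c in calls.items() if c.quality == "good"}
    used_names = sorted(
        {names[seq].assigned_name for c in good.values() for seq in c.alleles}
    )
    name_of = {seq: an.assigned_name for seq, an in names.items()}

    matrix_path = out_dir / "genotype_matrix.tsv"
    with open(matrix_path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(used_names) + "\n")
        for sample in sorted(good):
            present = {name_of[seq] for seq in good[sample].alleles}
            fh.write(
                sample
                + "\t"
                + "\t".join("1" if n in present else "0" for n in used_names)
                + "\n"
            )

    fasta_path = out_dir / "alleles.fasta"
    by_name = sorted(
        ((an.assigned_name, seq) for seq, an in names.items()
         if an.assigned_name in used_names),
    )
    with open(fasta_path, "w") as fh:
        for name, seq in by_name:
            fh.write(f">{name}\n{seq}\n")
    return {"matrix": matrix_path, "fasta": fasta_path}
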