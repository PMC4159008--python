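"""File formats: codon FASTA, reverse translation, TSV tables, manifests.

All machine outputs are UTF-8 TSVs with headers and stable column order;
intervals are half-open and coordinates 0-based codon columns.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import trees
from .alignment import CodonAlignment
from .codons import GAP_CODON, STOP_CODONS, translate_codon
from .fitting import BranchFit


def read_codon_fasta(path: str | os.PathLike) -> CodonAlignment:
    """Read an in-frame codon alignment (gap character '-', length % 3 == 0)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences")
    return CodonAlignment.from_sequences({r.id: str(r.seq) for r in records})


def write_codon_fasta(aln: CodonAlignment, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=label, description="") for label, seq in aln.to_sequences().items()
    ]
    SeqIO.write(records, str(path), "fasta")


def reverse_translate(
    protein_alignment: dict[str, str], cds_sequences: dict[str, str]
) -> CodonAlignment:
    """Thread each CDS back through its aligned protein sequence.

    Each amino acid is replaced by its source codon; protein gaps become the
    gap codon ``---``.  The ungapped protein must translate exactly from the
    CDS under the standard code (a trailing stop codon on the CDS is
    tolerated and dropped); any mismatch raises with sequence and position.
    """
    missing = set(protein_alignment) - set(cds_sequences)
    if missing:
        raise ValueError(f"no CDS provided for: {sorted(missing)}")
    out: dict[str, str] = {}
    for label, prot in protein_alignment.items():
        cds = cds_sequences[label].upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"{label}: CDS length {len(cds)} is not a multiple of 3")
        codon_list = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codon_list and codon_list[-1] in STOP_CODONS:
            codon_list = codon_list[:-1]
        residues = [a for a in prot if a != "-"]
        if len(codon_list) != len(residues):
            raise ValueError(
                f"{label}: CDS has {len(codon_list)} codons but protein has "
                f"{len(residues)} residues"
            )
        it = iter(range(len(residues)))
        pieces = []
        for aa in prot:
            if aa == "-":
                pieces.append(GAP_CODON)
                continue
            k = next(it)
            codon = codon_list[k]
            if codon in STOP_CODONS:
                raise ValueError(f"{label}: internal stop codon at codon {k}")
            trans = translate_codon(codon)
            if trans != aa.upper():
                raise ValueError(
                    f"{label}: codon {k} ({codon}) translates to {trans}, protein has {aa}"
                )
            pieces.append(codon)
        out[label] = "".join(pieces)
    return CodonAlignment.from_sequences(out)


def branch_fit_to_frame(fit: BranchFit) -> pd.DataFrame:
    """One row per branch: id, class, t, dn, ds."""
    rows = []
    for b in trees.BRANCHES:
        dn, ds = fit.per_branch_dnds[b]
        rows.append(
            {
                "branch": b,
                "omega_class": trees.CLASS_OF_BRANCH[b],
                "t": fit.tree.branch_lengths[b],
                "dn": dn,
                "ds": ds,
            }
        )
    return pd.DataFrame(rows)


def write_branch_fit(fit: BranchFit, path: str | os.PathLike) -> None:
    """Branch table TSV preceded by a '#'-commented header of fit-level values."""
    path = Path(path)
    header = (
        f"# kappa={fit.params.kappa:.6g}\tlogL={fit.log_likelihood:.6f}"
        f"\tconverged={fit.converged}\tn_restarts={fit.n_restarts_used}"
    )
    for cls, w in fit.params.omega_by_class.items():
        header += f"\tomega_{cls}={w:.6g}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        branch_fit_to_frame(fit).to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_branch_fit_frame(path: str | os.PathLike) -> tuple[pd.DataFrame, dict]:
    with open(path, encoding="utf-8") as fh:
        meta_line = fh.readline()
        meta = {}
        for item in meta_line.lstrip("# ").rstrip("\n").split("\t"):
            k, v = item.split("=", 1)
            meta[k] = v
        frame = pd.read_csv(fh, sep="\t")
    return frame, meta


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8", float_format="%.8g")


def write_manifest(manifest: dict, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path: str | os.PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
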