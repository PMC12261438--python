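"""Readers and writers for the package's file formats.

FASTA goes through Biopython; case is preserved because lowercase letters are
the soft-mask signal. Coordinates in every format are 0-based; intervals are
half-open. Data files written by the command-line tools carry a header
comment with the tool version and a hash of the resolved configuration.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .masking import ResidueMask
from .search import Hit
from .sequences import ProteinSequence
from .training import AlignedPair, pair_from_gapped


class FormatError(ValueError):
    """Malformed input file."""


def config_hash(config: dict) -> str:
    return hashlib.sha1(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def file_header(config: dict | None = None) -> str:
    h = config_hash(config or {})
    return f"# near v{__version__} config={h}"


# ------------------------------------------------------------------- FASTA

def read_fasta(path) -> list[ProteinSequence]:
    """Read sequences, preserving case; duplicate ids are an error."""
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            seqs.append(ProteinSequence(rec.id, str(rec.seq)))
        except ValueError as e:
            raise FormatError(str(e)) from e
    if not seqs:
        raise FormatError(f"no sequences in {path}")
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------- aligned pairs

def read_aligned_fasta(path) -> list[AlignedPair]:
    """Aligned-FASTA training pairs: two gapped records per pair, in order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records or len(records) % 2 != 0:
        raise FormatError(
            f"aligned-FASTA {path} must hold an even, positive number of records"
        )
    pairs = []
    for r, (ra, rb) in enumerate(zip(records[::2], records[1::2])):
        try:
            pairs.append(pair_from_gapped(ra.id, str(ra.seq), rb.id, str(rb.seq)))
        except ValueError as e:
            raise FormatError(f"record pair {r} ({ra.id}/{rb.id}): {e}") from e
    return pairs


def write_aligned_fasta(pairs: Iterable[AlignedPair], path) -> None:
    """Write pairs as gapped two-record blocks reconstructed from the columns."""
    records = []
    for p in pairs:
        ga, gb = _gapped_from_columns(p)
        records.append(SeqRecord(Seq(ga), id=p.seq_a.id, description=""))
        records.append(SeqRecord(Seq(gb), id=p.seq_b.id, description=""))
    SeqIO.write(records, str(path), "fasta")


def _gapped_from_columns(pair: AlignedPair) -> tuple[str, str]:
    a, b = pair.seq_a.residues, pair.seq_b.residues
    ga: list[str] = []
    gb: list[str] = []
    i = j = 0
    for ci, cj in pair.columns:
        while i < ci:
            ga.append(a[i]); gb.append("-"); i += 1
        while j < cj:
            ga.append("-"); gb.append(b[j]); j += 1
        ga.append(a[i]); gb.append(b[j]); i += 1; j += 1
    while i < len(a):
        ga.append(a[i]); gb.append("-"); i += 1
    while j < len(b):
        ga.append("-"); gb.append(b[j]); j += 1
    return "".join(ga), "".join(gb)


def read_columns_tsv(path, sequences: dict[str, ProteinSequence]) -> list[AlignedPair]:
    """3-column TSV pairs: seq_a_id, seq_b_id, comma-separated i:j columns."""
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 tab-separated fields")
            ida, idb, colspec = fields
            for sid in (ida, idb):
                if sid not in sequences:
                    raise FormatError(f"{path}:{ln}: unknown sequence id {sid!r}")
            try:
                cols = tuple(
                    tuple(int(x) for x in c.split(":")) for c in colspec.split(",") if c
                )
                pairs.append(AlignedPair(sequences[ida], sequences[idb], cols))
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from e
    return pairs


# ------------------------------------------------------------------- masks

def write_mask_bed(masks: Iterable[ResidueMask], path, config: dict | None = None) -> None:
    """Masked intervals as 3 columns (seq_id, start, end), 0-based half-open."""
    with open(path, "w") as fh:
        fh.write(file_header(config) + "\n")
        for m in masks:
            for start, end in m.intervals():
                fh.write(f"{m.seq_id}\t{start}\t{end}\n")


def apply_mask_as_lowercase(seq: ProteinSequence, mask: ResidueMask) -> ProteinSequence:
    if len(seq) != len(mask):
        raise ValueError("mask length mismatch")
    out = "".join(
        c.lower() if keep == 0 else c.upper()
        for c, keep in zip(seq.residues, mask.r)
    )
    return ProteinSequence(seq.id, out)


# -------------------------------------------------------------------- hits

def write_hits_tsv(hits: list[Hit], path, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(file_header(config) + "\n")
        fh.write("query_id\ttarget_id\tscore\tn_matches\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.target_id}\t{h.score:.6f}\t{h.n_matches}\n")


def read_hits_tsv(path) -> list[Hit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("query_id"):
                continue
            q, t, s, n = line.rstrip("\n").split("\t")
            hits.append(Hit(q, t, float(s), int(n)))
    return hits


# ------------------------------------------------------------- other files

def write_loss_csv(trace: list[tuple[int, float, float, float]], path,
                   config: dict | None = None) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(file_header(config) + "\n")
        w = csv.writer(fh)
        w.writerow(["step", "npair", "l2", "total"])
        for row in trace:
            w.writerow([row[0], f"{row[1]:.8g}", f"{row[2]:.8g}", f"{row[3]:.8g}"])


def write_curve_csv(curve, path, config: dict | None = None) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(file_header(config) + "\n")
        w = csv.writer(fh)
        w.writerow(["threshold", "filtration", "recall"])
        for t, f, r in zip(curve.thresholds, curve.filtration, curve.recall):
            w.writerow([f"{t:.8g}", f"{f:.8g}", f"{r:.8g}"])


def write_labels_tsv(positive_pairs: set, decoy_pairs: set, path,
                     config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(file_header(config) + "\n")
        fh.write("query_id\ttarget_id\tlabel\n")
        for q, t in sorted(positive_pairs):
            fh.write(f"{q}\t{t}\tpositive\n")
        for q, t in sorted(decoy_pairs):
            fh.write(f"{q}\t{t}\tdecoy\n")


def read_labels_tsv(path) -> tuple[set, set]:
    pos, dec = set(), set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or line.startswith("query_id") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 or fields[2] not in ("positive", "decoy"):
                raise FormatError(f"{path}:{ln}: bad label row")
            (pos if fields[2] == "positive" else dec).add((fields[0], fields[1]))
    return pos, dec


def read_evalue_tsv(path) -> dict[tuple[str, str], float]:
    """3-column evidence TSV: query_id, target_id, E-value."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 fields")
            out[(fields[0], fields[1])] = float(fields[2])
    return out


# -------------------------------------------------------------- embeddings

def write_embeddings(embs: dict[str, np.ndarray], path) -> None:
    """Array container keyed by sequence id (.npz)."""
    with open(path, "wb") as fh:
        np.savez(fh, **embs)


def read_embeddings(path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}
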