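"""Predicted miRNA->target interactions: file ingestion and a seed-match stand-in.

Real target prediction (miRanda/TargetScan-class tools) is upstream of this
package; interaction lists arrive as a tab-separated file with columns
``mirna_id, target_id, target_biotype`` (biotype lncRNA or mRNA) and are
treated as already merged across whatever tools produced them.

For fully self-contained runs on synthetic sequences, `seed_match_predict`
provides a deliberately minimal predictor: it reports a pair whenever the
reverse complement of the miRNA's 7-mer seed (positions 2-8) occurs in the
target sequence. No wobble pairing, no free-energy scoring, and site
multiplicity collapses to presence/absence, which is how the downstream
steps consume interactions anyway.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import ParseError, SequenceError
from .io import write_table

logger = logging.getLogger(__name__)

COLUMNS = ["mirna_id", "target_id", "target_biotype"]
_TARGET_BIOTYPES = {"lncRNA", "mRNA"}
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read and deduplicate an interaction TSV; rejects malformed rows with
    their line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file (header required)")
    header = lines[0].split("\t")
    if header != COLUMNS:
        raise ParseError(f"{path}:1: expected header {COLUMNS}, got {header}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        mirna_id, target_id, biotype = (f.strip() for f in fields)
        if biotype not in _TARGET_BIOTYPES:
            raise ParseError(
                f"{path}:{lineno}: target_biotype must be lncRNA or mRNA, got {biotype!r}"
            )
        if not mirna_id or not target_id:
            raise ParseError(f"{path}:{lineno}: empty identifier")
        rows.append((mirna_id, target_id, biotype))
    df = pd.DataFrame(rows, columns=COLUMNS)
    deduped = df.drop_duplicates(subset=["mirna_id", "target_id"], ignore_index=True).copy()
    if len(deduped) < len(df):
        logger.warning(
            "%s: removed %d duplicate miRNA-target pair(s)", path, len(df) - len(deduped)
        )
    deduped["source"] = "file"
    return deduped


def write_interactions(pairs: pd.DataFrame, path: str | Path) -> Path:
    return write_table(pairs[COLUMNS], path)


def _check_rna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGU")
    if bad:
        raise SequenceError(f"{what}: invalid RNA character(s) {sorted(bad)}")
    return seq


def seed_site(mirna_seq: str) -> str:
    """Reverse complement of the miRNA 7-mer seed (positions 2-8): the
    sequence a target must contain to be called."""
    seq = _check_rna(mirna_seq, "miRNA")
    if len(seq) < 8:
        raise SequenceError(f"miRNA sequence shorter than 8 nt ({len(seq)})")
    seed = seq[1:8]
    return seed.translate(_RNA_COMPLEMENT)[::-1]


def seed_match_predict(
    mirna_id: str, mirna_seq: str, targets: list[tuple[str, str, str]]
) -> pd.DataFrame:
    """Predict targets of one miRNA by exact 7-mer seed complementarity.

    ``targets`` is a list of (target_id, biotype, sequence). One pair per
    matching target regardless of site count.
    """
    site = seed_site(mirna_seq)
    rows = []
    for target_id, biotype, seq in targets:
        if biotype not in _TARGET_BIOTYPES:
            raise ParseError(f"target {target_id!r}: biotype must be lncRNA or mRNA")
        if site in _check_rna(seq, f"target {target_id!r}"):
            rows.append((mirna_id, target_id, biotype))
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["source"] = "seed_match"
    return df
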