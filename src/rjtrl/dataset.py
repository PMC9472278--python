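"""SMILES file handling and dataset preparation."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional

from .vocab import build_vocabulary, filter_dataset

logger = logging.getLogger(__name__)

__all__ = ["read_smiles_file", "write_smiles_file", "prepare_dataset"]


def read_smiles_file(path) -> List[str]:
    """One molecule per line; an optional tab-separated ID is dropped."""
    out = []
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise OSError(f"cannot read SMILES file {path}: {exc}") from exc
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split("\t")[0].split()[0])
    return out


def write_smiles_file(path, smiles) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in smiles))


def prepare_dataset(
    input_path,
    filtered_path: Optional[str] = None,
    vocab_path: Optional[str] = None,
    report_path: Optional[str] = None,
) -> dict:
    """Filter a raw SMILES file and build its vocabulary.

    Returns a report with per-rule rejection counts, the kept molecules and
    the vocabulary; optionally persists each artifact.
    """
    raw = read_smiles_file(input_path)
    kept, counts = filter_dataset(raw)
    vocab = build_vocabulary(kept) if kept else build_vocabulary([])
    report = {
        "input": str(input_path),
        "n_input": len(raw),
        "n_kept": len(kept),
        "rejections": {k: v for k, v in sorted(counts.items()) if k != "kept"},
        "n_voc": vocab.n_voc,
        "vocab_hash": vocab.content_hash(),
    }
    if filtered_path:
        write_smiles_file(filtered_path, kept)
    if vocab_path:
        vocab.save(vocab_path)
    if report_path:
        Path(report_path).write_text(json.dumps(report, indent=1))
    logger.info("prepare_dataset: %s", report)
    return {"report": report, "kept": kept, "vocabulary": vocab}
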