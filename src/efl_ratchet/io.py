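"""Shared readers/writers: Newick trees, FASTA, run manifests.

Tree handling is backed by dendropy; Newick output goes through a small
renderer with ``%g`` branch-length formatting so simple inputs round-trip
byte-identically.  Underscores in taxon labels are preserved verbatim.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import dendropy

__all__ = [
    "read_newick",
    "write_newick",
    "newick_string",
    "write_fasta",
    "write_manifest",
    "sha256_file",
]


class NewickError(ValueError):
    pass


def read_newick(path, default_length: float | None = None) -> dendropy.Tree:
    """Read a rooted Newick tree, names and lengths preserved.

    Branches without a length are an error unless ``default_length`` is
    given, in which case it is substituted.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise NewickError(f"{path}: malformed Newick ({exc})") from exc
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            if default_length is None:
                raise NewickError(
                    f"{path}: branch without length (pass default_length to fill)"
                )
            node.edge.length = default_length
    return tree


def parse_newick(text: str, default_length: float | None = None) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"malformed Newick ({exc})") from exc
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node and node.edge.length is None:
            if default_length is None:
                raise NewickError("branch without length")
            node.edge.length = default_length
    return tree


def _render(node) -> str:
    children = node.child_nodes()
    if children:
        inner = ",".join(_render(c) for c in children)
        label = node.taxon.label if node.taxon else (node.label or "")
        out = f"({inner}){label}"
    else:
        out = node.taxon.label if node.taxon else (node.label or "")
    if node.edge.length is not None:
        out += f":{node.edge.length:g}"
    return out


def newick_string(tree: dendropy.Tree) -> str:
    """Render a tree as one Newick line (``%g`` lengths, trailing ``;``)."""
    return _render(tree.seed_node) + ";"


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(newick_string(tree) + "\n", encoding="utf-8")


def write_fasta(ids, sequences, path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in zip(ids, sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: dict, outputs, path, inputs=()) -> dict:
    """JSON run manifest: tool version, config (incl. seed), checksums.

    The timestamp lives in its own key so reruns with identical config
    produce manifests identical everywhere else.
    """
    from . import __version__

    manifest = {
        "tool": "efl-ratchet",
        "version": __version__,
        "config": config,
        "seed": config.get("seed"),
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": {str(p): sha256_file(p) for p in outputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
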