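"""Splice fine- and coarse-scale tile embeddings into one vector per tile.

Every 0.5 MPP tile embedding is concatenated with the embedding of the
2.0 MPP tile covering the same physical position ([0.5 || 2.0], fine first),
so the downstream classifier sees both cellular detail and architectural
context for each patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contrastive import EmbeddingRecord
from .tiling import TileRef, parent_tile


class MultiscaleError(ValueError):
    pass


@dataclass
class MultiScaleEmbedding:
    ref: TileRef  # fine-scale (0.5 MPP) tile
    vector: np.ndarray  # [child_0.5 || parent_2.0]
    d_child: int
    d_parent: int


def splice(child_records: list[EmbeddingRecord],
           parent_records: list[EmbeddingRecord],
           parent_mpp: float = 2.0) -> list[MultiScaleEmbedding]:
    """Concatenate each fine tile's vector with its coarse parent's vector.

    Raises listing every orphan tile if any fine tile lacks a parent record.
    """
    parents = {(p.ref.row, p.ref.col): p for p in parent_records}
    orphans = [c.ref for c in child_records
               if (parent_tile(c.ref, parent_mpp).row,
                   parent_tile(c.ref, parent_mpp).col) not in parents]
    if orphans:
        locs = ", ".join(f"({t.row},{t.col})" for t in orphans[:20])
        raise MultiscaleError(f"{len(orphans)} fine tiles missing a parent record: {locs}")
    out = []
    for c in child_records:
        pref = parent_tile(c.ref, parent_mpp)
        p = parents[(pref.row, pref.col)]
        out.append(MultiScaleEmbedding(
            ref=c.ref,
            vector=np.concatenate([c.vector, p.vector]),
            d_child=c.vector.shape[0],
            d_parent=p.vector.shape[0],
        ))
    return out
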