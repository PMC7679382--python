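"""Keyword class inventory shared across all modules.

Every word of a pathology statement belongs to exactly one of four classes:
the specimen (body organ/region sampled), the acquisition procedure, the
pathologic diagnosis, or O ("otherwise"). The integer order is fixed
package-wide: (SPE, PRO, PAT, O) = (0, 1, 2, 3). Argmax tie-breaking,
model output layers, and metric tables all rely on this order.
"""

from __future__ import annotations

CLASSES: tuple[str, ...] = ("SPE", "PRO", "PAT", "O")
CLASS_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}
N_CLASSES: int = len(CLASSES)
O_INDEX: int = CLASS_TO_INDEX["O"]

#: The three keyword types, in class order, keyed by the JSONL field names.
KEYWORD_TYPES: tuple[str, ...] = ("specimen", "procedure", "pathology")
TYPE_TO_CLASS: dict[str, str] = dict(zip(KEYWORD_TYPES, CLASSES[:3]))
CLASS_TO_TYPE: dict[str, str] = {v: k for k, v in TYPE_TO_CLASS.items()}


def class_index(tag: str | int) -> int:
    """Return the integer index for a class given as tag string or index."""
    if isinstance(tag, str):
        return CLASS_TO_INDEX[tag]
    return int(tag)
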