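"""10-10 electrode-label arithmetic and contralateral bipolar pairing.

In the 10-10 naming scheme a label is a site prefix followed by either a
number (odd = left hemisphere, even = right) or ``z`` (midline).  A
contralateral bipolar derivation pairs a left electrode with its homolog on
the right (T7-T8, FT11-FT12, C3-C4, ...).  Midline electrodes have no
contralateral partner and are skipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$", re.IGNORECASE)


def parse_label(label: str) -> tuple[str, int | None]:
    """Split a 10-10 label into (prefix, index); index None for midline.

    Raises ValueError for labels that do not follow 10-10 naming.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"{label!r} does not follow 10-10 naming")
    prefix, idx = m.group(1), m.group(2)
    if idx.lower() == "z":
        return prefix, None
    return prefix, int(idx)


def is_midline(label: str) -> bool:
    return parse_label(label)[1] is None


def is_left(label: str) -> bool:
    idx = parse_label(label)[1]
    return idx is not None and idx % 2 == 1


def homolog(label: str) -> str | None:
    """Mirror a lateral label across the midline (T7 -> T8); None for midline."""
    prefix, idx = parse_label(label)
    if idx is None:
        return None
    return f"{prefix}{idx + 1 if idx % 2 == 1 else idx - 1}"


@dataclass
class Derivation:
    """Contralateral bipolar pair with its difference signal (left minus right)."""

    left_label: str
    right_label: str
    signal: np.ndarray | None = None
    name: str = field(init=False)

    def __post_init__(self) -> None:
        if is_midline(self.left_label) or is_midline(self.right_label):
            raise ValueError("midline electrodes cannot form a contralateral pair")
        if homolog(self.left_label) != self.right_label:
            raise ValueError(
                f"{self.left_label}/{self.right_label} are not homologous"
            )
        self.name = f"{self.left_label}-{self.right_label}"


def contralateral_pairs(
    labels: list[str],
) -> tuple[list[tuple[str, str]], list[str]]:
    """Pair left-hemisphere labels with their right homologs.

    Returns ``(pairs, skipped)`` where pairs are ``(left, right)`` tuples in
    the order the left electrode appears in ``labels`` and ``skipped`` lists
    midline electrodes, electrodes whose homolog is absent, and labels that
    do not parse as 10-10 names.
    """
    present = set(labels)
    pairs: list[tuple[str, str]] = []
    skipped: list[str] = []
    for lb in labels:
        try:
            prefix, idx = parse_label(lb)
        except ValueError:
            skipped.append(lb)
            continue
        if idx is None:
            skipped.append(lb)
            continue
        if idx % 2 == 1:  # left: claims the pair
            mate = homolog(lb)
            if mate in present:
                pairs.append((lb, mate))
            else:
                skipped.append(lb)
        else:  # right: skipped only if its left mate is missing
            if homolog(lb) not in present:
                skipped.append(lb)
    return pairs, skipped
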