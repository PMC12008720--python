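"""Electrode montages and reduced-density subsets.

The shipped 128-channel montage uses extended international 10-5 labels;
the 64/32/24 subsets are nested 10-10 / extended 10-20 reductions of it,
approximating the caps used in routine clinical EEG.  The label lists live
as editable one-label-per-line text files under ``taugraph/data`` and can
be replaced by site-specific sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

__all__ = ["ElectrodeSubset", "load_montage", "standard_subsets", "MONTAGE_SIZES"]

MONTAGE_SIZES = (128, 64, 32, 24)


@dataclass(frozen=True)
class ElectrodeSubset:
    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("subset labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)


def load_montage(size: int) -> ElectrodeSubset:
    """Load one of the shipped label sets (128, 64, 32 or 24 electrodes)."""
    if size not in MONTAGE_SIZES:
        raise ValueError(f"no shipped montage of size {size}; choose from {MONTAGE_SIZES}")
    text = resources.files("taugraph.data").joinpath(f"montage_{size}.txt").read_text()
    labels = tuple(line.strip() for line in text.splitlines() if line.strip())
    if len(labels) != size:
        raise RuntimeError(f"montage file for {size} electrodes holds {len(labels)} labels")
    return ElectrodeSubset(name=str(size), labels=labels)


def standard_subsets() -> dict[int, ElectrodeSubset]:
    """The nested 64/32/24 reductions of the 128-channel montage."""
    full = set(load_montage(128).labels)
    subsets = {}
    for size in (64, 32, 24):
        sub = load_montage(size)
        stray = [lab for lab in sub.labels if lab not in full]
        if stray:
            raise RuntimeError(f"subset {size} labels not in the 128 montage: {stray}")
        subsets[size] = sub
    return subsets
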