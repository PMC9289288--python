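"""Layered count container: gene x sample matrices for the spliced,
unspliced and ambiguous read pools, with the total defined as their
element-wise sum. Differential expression is run per layer while size
factors are always computed from the total."""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

LAYERS = ("spliced", "unspliced", "ambiguous")


@dataclass
class LayeredCounts:
    spliced: pd.DataFrame
    unspliced: pd.DataFrame
    ambiguous: pd.DataFrame

    def __post_init__(self) -> None:
        ref = self.spliced
        for name in ("unspliced", "ambiguous"):
            df = getattr(self, name)
            if not df.index.equals(ref.index) or not df.columns.equals(ref.columns):
                raise ValueError(f"layer {name} not aligned with spliced layer")
            if (df.to_numpy() < 0).any():
                raise ValueError(f"negative counts in layer {name}")
        if (ref.to_numpy() < 0).any():
            raise ValueError("negative counts in layer spliced")

    @property
    def genes(self) -> pd.Index:
        return self.spliced.index

    @property
    def samples(self) -> pd.Index:
        return self.spliced.columns

    @property
    def total(self) -> pd.DataFrame:
        return self.spliced + self.unspliced + self.ambiguous

    def layer(self, name: str) -> pd.DataFrame:
        if name == "total":
            return self.total
        if name not in LAYERS:
            raise KeyError(name)
        return getattr(self, name)

    def to_tsv(self, out_dir: str) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for name in (*LAYERS, "total"):
            path = os.path.join(out_dir, f"counts_{name}.tsv")
            self.layer(name).to_csv(path, sep="\t", index_label="gene_id")
            paths[name] = path
        return paths

    @classmethod
    def from_tsv(cls, out_dir: str) -> "LayeredCounts":
        frames = {}
        for name in LAYERS:
            path = os.path.join(out_dir, f"counts_{name}.tsv")
            frames[name] = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(**frames)
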