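"""Reference signature catalogs (signatures x 96 channel probabilities)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum import CHANNELS


@dataclass
class SignatureCatalog:
    """Rows are signatures; columns follow the canonical 96-channel order."""

    names: list[str]
    matrix: np.ndarray  # (n_signatures, 96), rows sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 96:
            raise ValueError(f"catalog matrix must be (n, 96), got {self.matrix.shape}")
        if len(self.names) != self.matrix.shape[0]:
            raise ValueError("names / matrix row mismatch")
        if (self.matrix < 0).any():
            raise ValueError("negative signature probability")
        if self.matrix.shape[0]:
            sums = self.matrix.sum(axis=1)
            if np.abs(sums - 1).max() > 1e-6:
                raise ValueError("signature rows must sum to 1 (renormalize on read)")

    @property
    def channel_order(self) -> tuple[str, ...]:
        return CHANNELS

    def __len__(self) -> int:
        return len(self.names)

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]

    def subset(self, names: list[str]) -> "SignatureCatalog":
        idx = [self.names.index(n) for n in names]
        return SignatureCatalog(list(names), self.matrix[idx])
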