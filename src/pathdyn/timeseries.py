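"""The multiomics time-series container.

One :class:`OmicsTimeSeries` holds a single strain's observed (or simulated)
trajectories: metabolite concentrations ``m[t]`` (s x n) and protein
concentrations ``p[t]`` (s x l) on a strictly increasing time grid of ``s``
points, in hours from induction. Concentrations are unit-agnostic but must be
nonnegative and consistent within a study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["OmicsTimeSeries"]


@dataclass(frozen=True)
class OmicsTimeSeries:
    """One strain's multiomics trajectories on a shared time grid.

    Parameters
    ----------
    strain_id : str
        Label for the strain (e.g. ``"L1"`` or ``"virtual-0042"``).
    times : (s,) array
        Sampling times in hours, strictly increasing, nonnegative.
    metabolites : (s, n) array
        Metabolite concentrations, one column per species.
    proteins : (s, l) array
        Protein (enzyme) concentrations, one column per species. May have
        zero columns for metabolomics-only series.
    metabolite_names, protein_names : list of str
        Column labels, in column order.
    """

    strain_id: str
    times: np.ndarray
    metabolites: np.ndarray
    proteins: np.ndarray
    metabolite_names: tuple[str, ...]
    protein_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        mets = np.atleast_2d(np.asarray(self.metabolites, dtype=float))
        prots = np.asarray(self.proteins, dtype=float)
        if prots.ndim == 1:
            prots = prots.reshape(len(times), -1)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "metabolites", mets)
        object.__setattr__(self, "proteins", prots)
        object.__setattr__(self, "metabolite_names", tuple(self.metabolite_names))
        object.__setattr__(self, "protein_names", tuple(self.protein_names))
        self._validate()

    def _validate(self) -> None:
        s = self.times.shape[0]
        if self.times.ndim != 1 or s < 1:
            raise ValidationError("times must be a nonempty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"times must be strictly increasing (strain {self.strain_id!r})"
            )
        if self.metabolites.shape != (s, len(self.metabolite_names)):
            raise ValidationError(
                f"metabolite matrix shape {self.metabolites.shape} does not match "
                f"{s} times x {len(self.metabolite_names)} names"
            )
        if self.proteins.shape != (s, len(self.protein_names)):
            raise ValidationError(
                f"protein matrix shape {self.proteins.shape} does not match "
                f"{s} times x {len(self.protein_names)} names"
            )
        for label, mat in (("metabolite", self.metabolites), ("protein", self.proteins)):
            if mat.size and not np.all(np.isfinite(mat)):
                raise ValidationError(f"non-finite {label} concentration in {self.strain_id!r}")
            if mat.size and np.any(mat < 0):
                row = int(np.argwhere(mat < 0)[0, 0])
                raise ValidationError(
                    f"negative {label} concentration at row {row} of strain {self.strain_id!r}"
                )

    # -- convenience ---------------------------------------------------

    @property
    def n_times(self) -> int:
        return self.times.shape[0]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_names)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_names)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def features(self) -> np.ndarray:
        """Concatenated (metabolites, proteins) rows, shape (s, n + l)."""
        return np.hstack([self.metabolites, self.proteins])

    def with_values(
        self,
        times: np.ndarray | None = None,
        metabolites: np.ndarray | None = None,
        proteins: np.ndarray | None = None,
    ) -> "OmicsTimeSeries":
        """Copy with some arrays replaced (names and strain id preserved)."""
        return replace(
            self,
            times=self.times if times is None else times,
            metabolites=self.metabolites if metabolites is None else metabolites,
            proteins=self.proteins if proteins is None else proteins,
        )

    def metabolite(self, name: str) -> np.ndarray:
        return self.metabolites[:, self.metabolite_names.index(name)]

    def protein(self, name: str) -> np.ndarray:
        return self.proteins[:, self.protein_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Wide table: strain, time, then met:<name> and prot:<name> columns."""
        data: dict[str, np.ndarray | str] = {
            "strain": self.strain_id,
            "time": self.times,
        }
        for j, name in enumerate(self.metabolite_names):
            data[f"met:{name}"] = self.metabolites[:, j]
        for j, name in enumerate(self.protein_names):
            data[f"prot:{name}"] = self.proteins[:, j]
        return pd.DataFrame(data)
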