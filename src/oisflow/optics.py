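"""Optical model for the modified Beer-Lambert system.

Absorbance changes at each LED wavelength are modelled as a linear
combination of oxy- and deoxyhemoglobin concentration changes:

    dA(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * D(lambda)

where ``eps`` are extinction coefficients and ``D`` a per-wavelength
differential pathlength factor (effective photon path, cm).  With three
wavelengths and two chromophores the system is overdetermined and solved
by pseudo-inverse in :mod:`oisflow.spectroscopy`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["OpticalModel", "MissingCoefficientError", "DegenerateModelError"]

#: Default differential pathlength factor, cm.  Lumps the true pathlength
#: and partial-volume effects into one effective constant; chosen so that
#: absorbance excursions are of order 0.1-1 at the concentration scale of
#: the default extinction table.  Cancels exactly in forward/inverse
#: round trips, so it only fixes the absolute concentration label.
DEFAULT_PATHLENGTH_CM = 0.005

CHROMOPHORES = ("HbO", "HbR")


class MissingCoefficientError(KeyError):
    """A requested wavelength has no extinction coefficients."""


class DegenerateModelError(ValueError):
    """The extinction/pathlength system is rank deficient."""


@dataclass(frozen=True)
class OpticalModel:
    """Extinction coefficients and pathlength factors per wavelength.

    Parameters
    ----------
    wavelengths : tuple of int
        LED wavelengths, nm.
    epsilon : ndarray, shape (n_wavelengths, 2)
        Extinction coefficients; columns are (HbO, HbR).  Units fix the
        concentration scale of all downstream outputs.
    pathlength : ndarray, shape (n_wavelengths,)
        Differential pathlength factor per wavelength (cm equivalent).
    """

    wavelengths: tuple[int, ...]
    epsilon: np.ndarray
    pathlength: np.ndarray

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=float)
        path = np.asarray(self.pathlength, dtype=float)
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "pathlength", path)
        n = len(self.wavelengths)
        if len(set(self.wavelengths)) != n:
            raise DegenerateModelError("wavelengths must be unique")
        if eps.shape != (n, len(CHROMOPHORES)):
            raise ValueError(f"epsilon must have shape ({n}, 2), got {eps.shape}")
        if path.shape != (n,):
            raise ValueError(f"pathlength must have shape ({n},)")
        if np.any(path <= 0):
            raise ValueError("pathlength factors must be > 0")
        if np.linalg.matrix_rank(self.design_matrix()) < len(CHROMOPHORES):
            raise DegenerateModelError(
                f"extinction system at wavelengths {self.wavelengths} is rank "
                "deficient; chromophores cannot be separated"
            )

    @classmethod
    def default(cls) -> "OpticalModel":
        """Model built from the packaged extinction table at 525/590/625 nm."""
        ref = resources.files("oisflow").joinpath("data/extinction_hb.tsv")
        rows = []
        for line in ref.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            wl, eo, er = line.split("\t")
            rows.append((int(wl), float(eo), float(er)))
        wavelengths = tuple(r[0] for r in rows)
        eps = np.array([[r[1], r[2]] for r in rows])
        path = np.full(len(rows), DEFAULT_PATHLENGTH_CM)
        return cls(wavelengths=wavelengths, epsilon=eps, pathlength=path)

    def coefficients(self, wavelength: int) -> np.ndarray:
        """(eps_HbO, eps_HbR) at one wavelength."""
        try:
            i = self.wavelengths.index(wavelength)
        except ValueError:
            raise MissingCoefficientError(
                f"no extinction coefficients for {wavelength} nm "
                f"(table covers {self.wavelengths})"
            ) from None
        return self.epsilon[i]

    def design_matrix(self) -> np.ndarray:
        """(eps * D) matrix, shape (n_wavelengths, 2)."""
        return self.epsilon * self.pathlength[:, None]

    def subset(self, wavelengths: tuple[int, ...]) -> "OpticalModel":
        idx = [self.wavelengths.index(w) if w in self.wavelengths else None
               for w in wavelengths]
        missing = [w for w, i in zip(wavelengths, idx) if i is None]
        if missing:
            raise MissingCoefficientError(
                f"no extinction coefficients for {missing} nm"
            )
        sel = np.array([i for i in idx if i is not None], dtype=int)
        return OpticalModel(
            wavelengths=tuple(wavelengths),
            epsilon=self.epsilon[sel],
            pathlength=self.pathlength[sel],
        )
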