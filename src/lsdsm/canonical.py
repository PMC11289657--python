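"""Canonical state-space structure and model parameters.

The longitudinal sub-process is an AR(M) process on ``m_y`` biomarkers,
written as a linear-Gaussian state space model in canonical (observable)
form.  With ``m_x = M * m_y`` hidden states, the observation matrix is
fixed at ``C = [I 0]`` so the leading ``m_y`` states are the true
(noise-free) biomarker values, the transition matrix is constrained to

    A = [ A_bar ]
        [ I   0 ]

and the process disturbance enters only through the leading block,
``W = G W_breve G^T`` with ``G = [I 0]^T``.  This constraint makes the
AR(M) parameterization identifiable: only ``A_bar`` (the AR coefficient
block) and the reduced disturbance covariance ``W_breve`` are free.

The survival sub-process is a proportional-hazards model whose linear
predictor combines baseline covariates (coefficients ``gamma``) and a
fixed linear functional ``H x`` of the hidden states (coefficients
``alpha``), h(t) = exp(gamma' omega + alpha' H x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

__all__ = [
    "CanonicalStructure",
    "ModelParameters",
    "build_canonical_structure",
]

_SYM_TOL = 1e-8
_PSD_TOL = -1e-10


@dataclass(frozen=True)
class CanonicalStructure:
    """Fixed (non-estimated) structure of the canonical AR(M) state space model.

    Parameters
    ----------
    m_y : int
        Number of observed biomarkers.
    M : int
        Autoregressive order.
    m_omega : int
        Number of baseline covariates entering the hazard (including an
        intercept column if the design carries one).
    H : ndarray of shape (m_alpha, m_x)
        Hazard-association matrix selecting/combining hidden states for
        the log-hazard.  Defaults to current-value association ``[I 0]``.
    """

    m_y: int
    M: int
    m_omega: int
    H: np.ndarray = field(repr=False)

    @property
    def m_x(self) -> int:
        return self.M * self.m_y

    @property
    def m_alpha(self) -> int:
        return self.H.shape[0]

    @property
    def C(self) -> np.ndarray:
        """Observation matrix [I 0], fixed."""
        C = np.zeros((self.m_y, self.m_x))
        C[:, : self.m_y] = np.eye(self.m_y)
        return C

    @property
    def G(self) -> np.ndarray:
        """Disturbance loading [I 0]^T, fixed."""
        return self.C.T.copy()

    def a_template(self) -> np.ndarray:
        """Boolean mask of the free entries of the assembled A matrix.

        Only the leading ``m_y`` rows are free; the lower block is the
        fixed shift structure [I 0].
        """
        mask = np.zeros((self.m_x, self.m_x), dtype=bool)
        mask[: self.m_y, :] = True
        return mask

    def lower_block(self) -> np.ndarray:
        """The fixed [I 0] shift block occupying the trailing rows of A."""
        lower = np.zeros(((self.M - 1) * self.m_y, self.m_x))
        if self.M > 1:
            lower[:, : (self.M - 1) * self.m_y] = np.eye((self.M - 1) * self.m_y)
        return lower

    def assemble_A(self, A_bar: np.ndarray) -> np.ndarray:
        """Stack the free AR block on top of the fixed shift block."""
        A_bar = np.atleast_2d(np.asarray(A_bar, dtype=float))
        if A_bar.shape != (self.m_y, self.m_x):
            raise ValueError(
                f"A_bar must be ({self.m_y}, {self.m_x}), got {A_bar.shape}"
            )
        return np.vstack([A_bar, self.lower_block()])


def build_canonical_structure(
    m_y: int, M: int, H: np.ndarray | None = None, m_omega: int = 1
) -> CanonicalStructure:
    """Build the fixed canonical structure for ``m_y`` biomarkers of AR order ``M``.

    ``H`` defaults to ``[I 0]`` (the hazard depends on the current true
    biomarker values only).  A custom ``H`` must have ``M * m_y`` columns.
    """
    if m_y < 1 or M < 1:
        raise ValueError("m_y and M must be positive integers")
    m_x = m_y * M
    if H is None:
        H = np.zeros((m_y, m_x))
        H[:, :m_y] = np.eye(m_y)
    else:
        H = np.atleast_2d(np.asarray(H, dtype=float))
        if H.shape[1] != m_x:
            raise ValueError(f"H must have {m_x} columns, got shape {H.shape}")
    return CanonicalStructure(m_y=m_y, M=M, m_omega=m_omega, H=H)


def _check_symmetric_psd(mat: np.ndarray, name: str) -> None:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=_SYM_TOL):
        raise ValueError(f"{name} is not symmetric within tolerance")
    eigvals = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    if eigvals.min(initial=0.0) < _PSD_TOL:
        raise ValueError(f"{name} has negative eigenvalue {eigvals.min()}")


@dataclass
class ModelParameters:
    """Estimable parameters theta of the joint model.

    theta = {x1_bar, W1_bar, A_bar, W_breve, V, gamma, alpha}; the fixed
    matrices C, G, H live on ``structure``.
    """

    structure: CanonicalStructure
    A_bar: np.ndarray
    W_breve: np.ndarray
    V: np.ndarray
    x1_bar: np.ndarray
    W1_bar: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        s = self.structure
        self.A_bar = np.atleast_2d(np.asarray(self.A_bar, dtype=float)).reshape(
            s.m_y, s.m_x
        )
        self.W_breve = np.atleast_2d(np.asarray(self.W_breve, dtype=float)).reshape(
            s.m_y, s.m_y
        )
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float)).reshape(s.m_y, s.m_y)
        self.x1_bar = np.asarray(self.x1_bar, dtype=float).reshape(s.m_x)
        self.W1_bar = np.atleast_2d(np.asarray(self.W1_bar, dtype=float)).reshape(
            s.m_x, s.m_x
        )
        self.gamma = np.asarray(self.gamma, dtype=float).reshape(s.m_omega)
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(s.m_alpha)

    # -- assembled fixed-structure matrices ---------------------------------
    @property
    def A(self) -> np.ndarray:
        return self.structure.assemble_A(self.A_bar)

    @property
    def W(self) -> np.ndarray:
        G = self.structure.G
        return G @ self.W_breve @ G.T

    def validate(self) -> None:
        """Check the canonical-form invariants; raise ValueError on violation."""
        _check_symmetric_psd(self.W_breve, "W_breve")
        _check_symmetric_psd(self.V, "V")
        _check_symmetric_psd(self.W1_bar, "W1_bar")
        A = self.A
        s = self.structure
        if s.M > 1:
            lower = A[s.m_y :, :]
            if not np.array_equal(lower, s.lower_block()):
                raise ValueError("lower block of A violates the canonical template")

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            structure=self.structure,
            A_bar=self.A_bar.copy(),
            W_breve=self.W_breve.copy(),
            V=self.V.copy(),
            x1_bar=self.x1_bar.copy(),
            W1_bar=self.W1_bar.copy(),
            gamma=self.gamma.copy(),
            alpha=self.alpha.copy(),
        )

    # -- flat views used by the EM convergence check ------------------------
    _FIELDS = ("x1_bar", "W1_bar", "A_bar", "W_breve", "V", "gamma", "alpha")

    def as_flat(self) -> np.ndarray:
        return np.concatenate([np.ravel(getattr(self, f)) for f in self._FIELDS])

    def max_abs_diff(self, other: "ModelParameters") -> float:
        return float(np.max(np.abs(self.as_flat() - other.as_flat())))

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        s = self.structure
        return {
            "structure": {
                "m_y": s.m_y,
                "M": s.M,
                "m_omega": s.m_omega,
                "H": s.H.tolist(),
            },
            "A_bar": self.A_bar.tolist(),
            "W_breve": self.W_breve.tolist(),
            "V": self.V.tolist(),
            "x1_bar": self.x1_bar.tolist(),
            "W1_bar": self.W1_bar.tolist(),
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        sd = d["structure"]
        structure = build_canonical_structure(
            m_y=int(sd["m_y"]),
            M=int(sd["M"]),
            H=np.asarray(sd["H"], dtype=float),
            m_omega=int(sd["m_omega"]),
        )
        return cls(
            structure=structure,
            A_bar=np.asarray(d["A_bar"], dtype=float),
            W_breve=np.asarray(d["W_breve"], dtype=float),
            V=np.asarray(d["V"], dtype=float),
            x1_bar=np.asarray(d["x1_bar"], dtype=float),
            W1_bar=np.asarray(d["W1_bar"], dtype=float),
            gamma=np.asarray(d["gamma"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
        )

    def to_json(self, path, **meta) -> None:
        doc = self.to_dict()
        if meta:
            doc["fit"] = meta
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
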