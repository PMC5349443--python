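"""Declarative specification of covariance-structure (SEM) models.

A model is described over a set of observed variables and optional latent
factors by three pattern matrices in the reticular (RAM) form:

* ``A`` — directed paths (row = target, column = source); holds factor
  loadings (latent -> indicator) and structural regressions,
* ``S`` — symmetric covariances; holds factor variances/covariances,
  unique (residual) variances and any user-listed residual covariances,
* ``M`` — means / intercepts (used only when means are modelled, e.g. FIML).

The model-implied covariance of the observed variables is
``Sigma = F (I - A)^-1 S (I - A)^-T F'`` with ``F`` selecting observed rows,
and the implied mean is ``mu = F (I - A)^-1 M``.

Every free entry carries a parameter label; entries sharing a label share a
single free parameter, which is how equality constraints (within a group and
across groups in multi-group fits) are expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SemSpec", "CompiledSpec", "SpecError"]


class SpecError(ValueError):
    """Raised for inconsistent or unidentified model specifications."""


@dataclass
class _Entry:
    mat: str  # "A", "S" or "M"
    i: int
    j: int
    name: str | None  # None => fixed
    value: float | None  # fixed value (when name is None)
    start: float


class SemSpec:
    """Builder for a latent-variable / path model.

    Parameters
    ----------
    observed
        Names of the observed variables, in the column order of the data
        they will be fit to.
    latents
        Names of latent factors (may be empty for pure path models).
    """

    def __init__(self, observed, latents=()):
        self.observed = list(observed)
        self.latents = list(latents)
        if len(set(self.observed + self.latents)) != len(self.observed) + len(self.latents):
            raise SpecError("variable names must be unique across observed and latent sets")
        self._index = {v: k for k, v in enumerate(self.observed + self.latents)}
        self._entries: list[_Entry] = []
        self._param_kind: dict[str, str] = {}

    # -- builder methods ---------------------------------------------------

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_variables(self) -> int:
        return len(self.observed) + len(self.latents)

    def _idx(self, var: str) -> int:
        try:
            return self._index[var]
        except KeyError:
            raise SpecError(f"unknown variable {var!r}") from None

    def _add(self, mat, i, j, name, value, start, kind):
        if name is not None:
            prev = self._param_kind.get(name)
            if prev is not None and prev != kind:
                raise SpecError(f"parameter {name!r} reused with a different role ({prev} vs {kind})")
            self._param_kind[name] = kind
        self._entries.append(_Entry(mat, i, j, name, value, start))

    def add_loading(self, factor, indicator, *, value=None, start=0.7, name=None):
        """Loading of ``indicator`` on latent ``factor`` (free unless ``value`` given)."""
        if factor not in self.latents:
            raise SpecError(f"{factor!r} is not a latent factor")
        if value is None and name is None:
            name = f"l_{factor}_{indicator}"
        self._add("A", self._idx(indicator), self._idx(factor),
                  None if value is not None else name, value, start, "path")
        return self

    def add_regression(self, outcome, predictor, *, value=None, start=0.0, name=None):
        """Directed structural path ``predictor -> outcome``."""
        if value is None and name is None:
            name = f"b_{outcome}_{predictor}"
        self._add("A", self._idx(outcome), self._idx(predictor),
                  None if value is not None else name, value, start, "path")
        return self

    def add_variance(self, var, *, value=None, start=0.5, name=None):
        if value is None and name is None:
            name = f"v_{var}"
        k = self._idx(var)
        self._add("S", k, k, None if value is not None else name, value, start, "variance")
        return self

    def add_covariance(self, a, b, *, value=None, start=0.0, name=None):
        if a == b:
            raise SpecError("use add_variance for diagonal entries")
        if value is None and name is None:
            name = f"c_{a}_{b}"
        self._add("S", self._idx(a), self._idx(b),
                  None if value is not None else name, value, start, "covariance")
        return self

    def add_mean(self, var, *, value=None, start=0.0, name=None):
        if value is None and name is None:
            name = f"m_{var}"
        self._add("M", self._idx(var), 0, None if value is not None else name, value, start, "mean")
        return self

    @property
    def has_means(self) -> bool:
        return any(e.mat == "M" for e in self._entries)

    # -- compilation -------------------------------------------------------

    def compile(self) -> "CompiledSpec":
        v = self.n_variables
        A0 = np.zeros((v, v))
        S0 = np.zeros((v, v))
        M0 = np.zeros(v)
        names: list[str] = []
        slots: dict[str, list[tuple[str, int, int]]] = {}
        starts: dict[str, float] = {}
        for e in self._entries:
            if e.name is None:
                if e.mat == "A":
                    A0[e.i, e.j] = e.value
                elif e.mat == "S":
                    S0[e.i, e.j] = e.value
                    S0[e.j, e.i] = e.value
                else:
                    M0[e.i] = e.value
            else:
                if e.name not in slots:
                    names.append(e.name)
                    slots[e.name] = []
                    starts[e.name] = e.start
                slots[e.name].append((e.mat, e.i, e.j))
        self._check_identification(A0, S0, slots)
        kinds = [self._param_kind[n] for n in names]
        return CompiledSpec(
            observed=list(self.observed), latents=list(self.latents),
            A0=A0, S0=S0, M0=M0, names=names, kinds=kinds,
            slots=[slots[n] for n in names],
            starts=np.array([starts[n] for n in names], float),
            has_means=self.has_means,
        )

    def _check_identification(self, A0, S0, slots):
        p = self.n_observed
        fixed_load = set()
        for k, lat in enumerate(self.latents):
            col = p + k
            if S0[col, col] != 0:
                fixed_load.add(lat)
            elif np.any(A0[:, col] != 0):
                fixed_load.add(lat)
        for lat in self.latents:
            if lat not in fixed_load:
                raise SpecError(
                    f"latent {lat!r} is not identified: fix its variance or one loading")


@dataclass
class CompiledSpec:
    """Frozen, index-based form of a :class:`SemSpec` ready for estimation."""

    observed: list[str]
    latents: list[str]
    A0: np.ndarray
    S0: np.ndarray
    M0: np.ndarray
    names: list[str]
    kinds: list[str]
    slots: list[list[tuple[str, int, int]]]
    starts: np.ndarray
    has_means: bool
    _variance_mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self._variance_mask = np.array([k == "variance" for k in self.kinds])

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_free(self) -> int:
        return len(self.names)

    def assemble(self, theta: np.ndarray):
        """Build (A, S, M) from a raw-scale parameter vector."""
        A = self.A0.copy()
        S = self.S0.copy()
        M = self.M0.copy()
        for val, slot in zip(theta, self.slots):
            for mat, i, j in slot:
                if mat == "A":
                    A[i, j] = val
                elif mat == "S":
                    S[i, j] = val
                    S[j, i] = val
                else:
                    M[i] = val
        return A, S, M

    # variance parameters are optimized on the log scale for positivity
    def to_internal(self, theta_raw: np.ndarray) -> np.ndarray:
        t = np.array(theta_raw, float)
        m = self._variance_mask
        t[m] = np.log(np.maximum(t[m], 1e-10))
        return t

    def to_raw(self, theta_int: np.ndarray) -> np.ndarray:
        t = np.array(theta_int, float)
        m = self._variance_mask
        t[m] = np.exp(t[m])
        return t

    def jac_raw_wrt_internal(self, theta_int: np.ndarray) -> np.ndarray:
        d = np.ones_like(theta_int)
        m = self._variance_mask
        d[m] = np.exp(theta_int[m])
        return d
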