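"""Synthetic expression matrices with a planted pivotal-community structure.

The generator emulates the pipeline's natural input: one co-expression
module of genes containing the target, inside which a tighter core of
mutually well-correlated genes (the planted "pivotal community") is hidden,
optionally surrounded by weakly correlated background genes. Subjects are
independent draws from a zero-mean multivariate normal whose correlation
matrix has a block factor structure: every core gene i carries a loading
l_i drawn around sqrt(r_core), every other module gene a loading m_j drawn
around sqrt(r_module), and pairwise correlations are l_i*l_j within the
core, m_i*m_j within the rest of the module, and alpha*l_i*m_j across
(alpha fixed so the cross-block mean equals r_module). The expected pairwise
|r| therefore equals the design's block values exactly, while individual
pairs spread around them the way real co-expression modules do.

That spread matters: with perfectly uniform correlations the core turns
into a complete clique just below r_core, internal betweenness vanishes,
and the planted community carries no pivotality signal for the index that
is supposed to find it. The default loading spread (0.05) is the largest
value that keeps the three planted correlation classes disjoint
(core pairs stay above every cross- and module-pair) for the default
r_core 0.6 / r_module 0.35; ``loading_spread=0`` recovers the plain
equicorrelated design. Defaults mirror the study scale: 199 subjects, an
85-gene module with a 28-gene core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = ["PlantedDesign", "generate"]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted-core design.

    ``noise_sd`` adds independent per-cell Gaussian measurement noise after
    the correlated draw; it attenuates all planted correlations toward 0 by
    the factor 1/(1+noise_sd^2), default off.
    """

    n_subjects: int = 199
    core_genes: int = 28
    module_genes: int = 85
    background_genes: int = 0
    r_core: float = 0.6
    r_module: float = 0.35
    r_background: float = 0.05
    loading_spread: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0
    target_name: str = "DRD2"
    log_intensity_scale: bool = False  # per-gene affine transform for I/O realism

    def __post_init__(self) -> None:
        if not 0 <= self.r_background < self.r_module < self.r_core < 1:
            raise ValueError(
                "need 0 <= r_background < r_module < r_core < 1, got "
                f"{self.r_background}, {self.r_module}, {self.r_core}"
            )
        if not 3 <= self.core_genes <= self.module_genes:
            raise ValueError("core must hold >=3 genes and fit inside the module")
        if self.n_subjects < 2 or self.background_genes < 0 or self.noise_sd < 0:
            raise ValueError("invalid design counts")
        if not 0 <= self.loading_spread < min(
            np.sqrt(self.r_module), 1 - np.sqrt(self.r_core)
        ):
            raise ValueError("loading_spread too large for the block levels")

    @property
    def n_genes(self) -> int:
        return self.module_genes + self.background_genes

    def correlation_matrix(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Planted correlation matrix; loadings drawn from ``rng`` when the
        spread is nonzero (pass the generator used for the data draw so one
        seed fixes everything)."""
        if rng is None:
            rng = np.random.default_rng(self.seed)
        n, nc, nm = self.n_genes, self.core_genes, self.module_genes
        d = self.loading_spread
        l = rng.uniform(np.sqrt(self.r_core) - d, np.sqrt(self.r_core) + d, nc)
        m = rng.uniform(np.sqrt(self.r_module) - d, np.sqrt(self.r_module) + d, nm - nc)
        # cross-block factor correlation chosen so E[|r|] across blocks = r_module
        alpha = self.r_module / np.sqrt(self.r_core * self.r_module)
        c = np.full((n, n), self.r_background)
        c[:nc, :nc] = np.outer(l, l)
        c[nc:nm, nc:nm] = np.outer(m, m)
        c[:nc, nc:nm] = alpha * np.outer(l, m)
        c[nc:nm, :nc] = c[:nc, nc:nm].T
        np.fill_diagonal(c, 1.0)
        return c

    def gene_names(self) -> list[str]:
        names = [self.target_name]
        names += [f"G{i:03d}" for i in range(2, self.module_genes + 1)]
        names += [f"B{i:03d}" for i in range(1, self.background_genes + 1)]
        return names


def _nearest_pd(a: np.ndarray) -> np.ndarray:
    """Higham-style repair: clip negative eigenvalues, restore unit diagonal."""
    w, v = np.linalg.eigh((a + a.T) / 2)
    w = np.clip(w, 1e-10, None)
    b = (v * w) @ v.T
    d = np.sqrt(np.diagonal(b))
    return b / np.outer(d, d)


def generate(design: PlantedDesign) -> tuple[ExpressionMatrix, frozenset[str]]:
    """Draw a genes x subjects matrix; returns it with the planted core set.

    Deterministic per ``design.seed``; the target gene is core member 0.
    """
    rng = np.random.default_rng(design.seed)
    corr = design.correlation_matrix(rng)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        repaired = _nearest_pd(corr)
        try:
            chol = np.linalg.cholesky(repaired)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ValueError("planted correlation matrix is not repairable") from exc
    z = rng.standard_normal((design.n_subjects, design.n_genes))
    x = (z @ chol.T).T  # genes x subjects
    if design.noise_sd > 0:
        x = x + design.noise_sd * rng.standard_normal(x.shape)
    if design.log_intensity_scale:
        offsets = rng.uniform(4.0, 12.0, size=design.n_genes)
        scales = rng.uniform(0.5, 2.0, size=design.n_genes)
        x = x * scales[:, None] + offsets[:, None]
    names = design.gene_names()
    matrix = ExpressionMatrix(
        gene_ids=names,
        subject_ids=[f"S{j + 1:03d}" for j in range(design.n_subjects)],
        values=x,
    )
    core = frozenset(names[: design.core_genes])
    return matrix, core
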