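"""Ground-truthed simulator of a branching chromaffin-like differentiation.

The generator emulates SmartSeq2-depth single-cell counts over a small lineage
tree: a Schwann-cell-precursor-like root that splits into a glial branch and a
bridge that itself bifurcates into two chromaffin terminal fates (three
terminal segments in the default configuration).  Per gene, spliced and
unspliced abundances follow the standard one-gene transcription kinetics

    du/dt = alpha(t) - beta * u,      ds/dt = beta * u - gamma * s,

integrated exactly along each root-to-leaf path for piecewise-constant
alpha, with logistic activation (and deactivation) programs in pseudotime.
Counts are negative-binomial with gene-level dispersion; 92 ERCC spike-in
genes are added at cell-independent expected abundance.  Two antagonistic
early fate modules (glial-biased and chromaffin-biased gene sets) are driven
in opposite directions by a per-cell latent bias, planting the negative
module-module correlation in root cells that the bias stage measures.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .container import CountContainer

__all__ = [
    "SegmentDef",
    "LineageSpec",
    "GroundTruth",
    "ConfigurationError",
    "default_lineage",
    "simulate_dataset",
    "make_qc_fixture",
]

N_ERCC = 92
_DT = 0.01  # ODE grid step, pseudotime units


class ConfigurationError(ValueError):
    """Raised when a lineage specification is internally inconsistent."""


@dataclass(frozen=True)
class SegmentDef:
    name: str
    parent: str | None
    t_start: float
    t_end: float
    terminal: bool = False


@dataclass
class LineageSpec:
    """Branching lineage plus per-gene kinetic and program parameters.

    ``genes`` columns: gene (id), kind (background | decay | program |
    module_glial | module_chc), segment (program segment or "root"), t_on
    (activation midpoint; deactivation midpoint for decay genes), plateau
    (transcription-rate plateau), beta, gamma (kinetic rates), theta
    (NB dispersion size).
    """

    segments: list[SegmentDef]
    genes: pd.DataFrame
    modules: dict[str, list[str]] = field(default_factory=dict)
    # fold-activation of a module by aligned bias is strong; repression by
    # opposing bias is bounded (expression cannot fall far below a lowly
    # expressed baseline) — the asymmetry also keeps the module's dataset
    # average above its level in unbiased cells, as for real fate markers
    bias_kappa: float = 2.0
    bias_kappa_neg: float = 0.3
    # root-cell mixture: unbiased (latent b ~ N(0, 0.25)), glial-biased and
    # chromaffin-biased (|b| ~ U(0.6, 1)) fractions
    bias_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    logistic_tau: float = 0.08
    ercc_depth_fraction: float = 0.05

    def __post_init__(self) -> None:
        names = {s.name for s in self.segments}
        if "root" not in names:
            raise ConfigurationError("lineage must contain a 'root' segment")
        for s in self.segments:
            if s.name != "root" and s.parent not in names:
                raise ConfigurationError(f"segment {s.name!r} has unknown parent")
            if s.t_end <= s.t_start:
                raise ConfigurationError(f"segment {s.name!r} span must be positive")
        if (self.genes["gamma"] <= 0).any() or (self.genes["beta"] <= 0).any():
            raise ConfigurationError("kinetic rates beta, gamma must be positive")
        known = set(self.genes["gene"])
        for mod, members in self.modules.items():
            unknown = [g for g in members if g not in known]
            if unknown:
                raise ConfigurationError(
                    f"module {mod!r} references unknown genes: {unknown[:5]}"
                )

    @property
    def terminal_segments(self) -> list[str]:
        return [s.name for s in self.segments if s.terminal]

    def paths(self) -> dict[str, list[str]]:
        """Root-to-leaf segment chains, one per terminal segment."""
        by_name = {s.name: s for s in self.segments}
        out = {}
        for term in self.terminal_segments:
            chain = [term]
            while by_name[chain[-1]].parent is not None:
                chain.append(by_name[chain[-1]].parent)
            out[term] = chain[::-1]
        return out


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth recorded by the simulator."""

    cells: pd.DataFrame  # cell_id, true_time, segment, bias_label, bias, path
    genes: pd.DataFrame  # gene, kind, segment, t_on, plateau, beta, gamma, theta
    low_quality: np.ndarray  # positions of planted low-quality cells

    @property
    def terminal_segments(self) -> list[str]:
        segs = self.genes.attrs.get("terminal_segments")
        return list(segs) if segs is not None else []

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cols = ["true_time", "segment", "bias_label"]
        self.cells[cols].to_csv(path / "truth_cells.tsv", sep="\t")
        payload = {
            "genes": self.genes.to_dict(orient="list"),
            "low_quality": self.low_quality.tolist(),
        }
        (path / "truth_genes.json").write_text(json.dumps(payload))


def default_lineage(
    n_genes: int = 8000,
    n_program_per_segment: int = 60,
    n_module: int = 20,
    decay_fraction: float = 0.40,
    spec_seed: int = 0,
) -> LineageSpec:
    """Default three-terminal lineage: root -> glial; root -> bridge -> {ChC-A, ChC-B}.

    Pseudotime spans are in arbitrary units; gene plateaus are log-normal so
    that a cell sequenced at SmartSeq2 depth detects on the order of 7000
    genes.  ``decay_fraction`` of background genes switch off along
    pseudotime, giving progenitors their higher transcriptional diversity.
    """
    rng = np.random.default_rng(spec_seed)
    segments = [
        SegmentDef("root", None, 0.0, 1.0),
        SegmentDef("glial", "root", 1.0, 2.0, terminal=True),
        SegmentDef("bridge", "root", 1.0, 1.5),
        SegmentDef("ChC-A", "bridge", 1.5, 2.5, terminal=True),
        SegmentDef("ChC-B", "bridge", 1.5, 2.5, terminal=True),
    ]
    # every segment carries a transcriptional program, including root: SCP
    # maturation genes switch on across the root span, so the source of the
    # differentiation flow is identifiable from kinetics
    prog_segments = ["root", "glial", "bridge", "ChC-A", "ChC-B"]
    n_prog = n_program_per_segment * len(prog_segments)
    n_mod = 2 * n_module
    n_bg = n_genes - n_prog - n_mod
    if n_bg < 100:
        raise ConfigurationError("n_genes too small for the default programs")
    n_decay = int(round(decay_fraction * n_bg))

    rows = []
    k = 0

    def plateau() -> float:
        return float(np.exp(rng.normal(1.0, 1.2)))

    for _ in range(n_bg - n_decay):
        rows.append((f"g{k:05d}", "background", "root", 0.0, plateau()))
        k += 1
    for _ in range(n_decay):
        t_off = float(rng.uniform(0.3, 1.5))
        rows.append((f"g{k:05d}", "decay", "root", t_off, plateau()))
        k += 1
    seg_span = {s.name: (s.t_start, s.t_end) for s in segments}
    for seg in prog_segments:
        lo, hi = seg_span[seg]
        for _ in range(n_program_per_segment):
            t_on = float(rng.uniform(lo + 0.1, hi - 0.1))
            rows.append((f"g{k:05d}", "program", seg, t_on, plateau() * 2.0))
            k += 1
    # fate-bias modules: constitutively transcribed, pushed up/down by the
    # per-cell latent bias — the trend along each branch comes from the bias,
    # not from an activation program
    glial_mod, chc_mod = [], []
    for kind, bucket in (("module_glial", glial_mod), ("module_chc", chc_mod)):
        for _ in range(n_module):
            g = f"g{k:05d}"
            rows.append((g, kind, "root", 0.0, plateau() * 2.0))
            bucket.append(g)
            k += 1
    genes = pd.DataFrame(rows, columns=["gene", "kind", "segment", "t_on", "plateau"])
    genes["beta"] = 5.0
    genes["gamma"] = np.exp(rng.normal(0.0, 0.3, len(genes)))
    genes["theta"] = np.exp(rng.normal(np.log(3.0), 0.5, len(genes)))
    spec = LineageSpec(
        segments=segments,
        genes=genes,
        modules={"glial": glial_mod, "chromaffin": chc_mod},
    )
    return spec


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _alpha_on_path(spec: LineageSpec, path: list[str], t: np.ndarray) -> np.ndarray:
    """Transcription rate alpha(t) for every gene along one path; (n_t, n_genes)."""
    g = spec.genes
    tau = spec.logistic_tau
    alpha = np.zeros((t.size, len(g)))
    on_path = g["segment"].isin(path).to_numpy()
    kind = g["kind"].to_numpy()
    plateau = g["plateau"].to_numpy()
    t_on = g["t_on"].to_numpy()
    bg = kind == "background"
    alpha[:, bg] = plateau[bg][None, :]
    dec = kind == "decay"
    alpha[:, dec] = plateau[dec][None, :] * (
        1.0 - _logistic((t[:, None] - t_on[dec][None, :]) / tau)
    ) + 0.002 * plateau[dec][None, :]
    mod = (kind == "module_glial") | (kind == "module_chc")
    alpha[:, mod] = plateau[mod][None, :]
    act = kind == "program"
    live = act & on_path
    alpha[:, live] = plateau[live][None, :] * _logistic(
        (t[:, None] - t_on[live][None, :]) / tau
    )
    return alpha


def _solve_path(spec: LineageSpec, path: list[str], t_end: float):
    """Exact piecewise-constant-alpha integration of the kinetic ODE.

    Returns (t_grid, u, s) with u, s of shape (n_t, n_genes), starting from
    the steady state of alpha(0).
    """
    t = np.arange(0.0, t_end + _DT / 2, _DT)
    alpha = _alpha_on_path(spec, path, t)
    beta = spec.genes["beta"].to_numpy()
    gamma = spec.genes["gamma"].to_numpy()
    u = np.empty_like(alpha)
    s = np.empty_like(alpha)
    u[0] = alpha[0] / beta
    s[0] = alpha[0] / gamma
    eb = np.exp(-beta * _DT)
    eg = np.exp(-gamma * _DT)
    # with alpha constant over a step: u -> a/b + (u - a/b) e^{-b dt};
    # s -> a/g + (s - a/g) e^{-g dt} + b (u - a/b)/(g - b) (e^{-b dt} - e^{-g dt})
    denom = gamma - beta
    degenerate = np.abs(denom) < 1e-9
    denom = np.where(degenerate, 1.0, denom)
    for i in range(1, t.size):
        a = alpha[i - 1]
        du = u[i - 1] - a / beta
        cross = beta * du / denom * (eb - eg)
        cross = np.where(degenerate, beta * du * _DT * eb, cross)
        u[i] = a / beta + du * eb
        s[i] = a / gamma + (s[i - 1] - a / gamma) * eg + cross
    return t, u, s


def _sample_nb(rng: np.random.Generator, mean: np.ndarray,
               theta: np.ndarray) -> np.ndarray:
    """Gamma-Poisson sampling of NB counts; mean is (cells, genes)."""
    mean = np.maximum(mean, 0.0)
    shape = np.broadcast_to(theta, mean.shape)
    lam = np.where(mean > 0, rng.gamma(shape, np.where(mean > 0, mean, 1.0) / shape), 0.0)
    return rng.poisson(lam).astype(np.int64)


def simulate_dataset(
    spec: LineageSpec,
    n_cells: int = 1000,
    depth: float = 2.0e5,
    seed: int = 0,
) -> tuple[CountContainer, GroundTruth]:
    """Simulate a branching dataset with spliced/unspliced layers and truth.

    Cells are placed uniformly along root-to-leaf paths (paths drawn
    uniformly); per-cell expected library size over cellular genes equals
    ``depth`` and ERCC spike-ins are appended at a cell-independent expected
    abundance.
    """
    if n_cells < 50:
        raise ValueError("n_cells must be >= 50")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    paths = spec.paths()
    terms = sorted(paths)
    by_name = {s.name: s for s in spec.segments}

    solutions = {
        term: _solve_path(spec, paths[term], by_name[term].t_end) for term in terms
    }

    # --- cells: path, time, latent fate bias -------------------------------
    path_of = rng.choice(len(terms), size=n_cells)
    t_of = np.array(
        [rng.uniform(0.0, by_name[terms[p]].t_end) for p in path_of]
    )
    seg_of = np.empty(n_cells, dtype=object)
    for i, p in enumerate(path_of):
        for segname in paths[terms[p]]:
            s = by_name[segname]
            if s.t_start <= t_of[i] <= s.t_end:
                seg_of[i] = segname
        if seg_of[i] is None:
            seg_of[i] = paths[terms[p]][-1]

    # root cells: a mixture of truly unbiased cells (small latent bias, so
    # the modules covary weakly but assignment should stay SCP) and
    # committed-bias cells; branch cells inherit the bias of their side
    glial_terms = {t for t in terms if "glial" in t.lower()}
    bias = np.empty(n_cells)
    in_root = seg_of == "root"
    n_root = int(in_root.sum())
    comp = rng.choice(3, size=n_root, p=list(spec.bias_fractions))
    b_root = np.where(
        comp == 0,
        np.clip(rng.normal(0.0, 0.25, n_root), -0.5, 0.5),
        np.where(comp == 1, 1.0, -1.0) * rng.uniform(0.6, 1.0, n_root),
    )
    bias[in_root] = b_root
    for i in np.where(~in_root)[0]:
        sign = 1.0 if terms[path_of[i]] in glial_terms else -1.0
        bias[i] = np.clip(sign + rng.normal(0.0, 0.1), -1.2, 1.2)
    bias_label = np.full(n_cells, "none", dtype=object)
    root_idx = np.where(in_root)[0]
    bias_label[root_idx[comp == 1]] = "glial"
    bias_label[root_idx[comp == 2]] = "chromaffin"

    # --- expected abundances ----------------------------------------------
    n_g = len(spec.genes)
    kind = spec.genes["kind"].to_numpy()
    mod_sign = np.zeros(n_g)
    mod_sign[kind == "module_glial"] = 1.0
    mod_sign[kind == "module_chc"] = -1.0

    mean_u = np.empty((n_cells, n_g))
    mean_s = np.empty((n_cells, n_g))
    for p, term in enumerate(terms):
        idx = np.where(path_of == p)[0]
        if idx.size == 0:
            continue
        t_grid, u, s = solutions[term]
        gi = np.clip(np.rint(t_of[idx] / _DT).astype(int), 0, t_grid.size - 1)
        mean_u[idx] = u[gi]
        mean_s[idx] = s[gi]
    # per-cell constant bias scales alpha, hence u and s, exactly;
    # asymmetric response: aligned bias activates more than opposing
    # bias represses
    expo = bias[:, None] * mod_sign[None, :]
    mult = np.exp(
        np.where(expo >= 0, spec.bias_kappa * expo, spec.bias_kappa_neg * expo)
    )
    mean_u *= mult
    mean_s *= mult

    rel = mean_u + mean_s
    scale = depth / np.maximum(rel.sum(axis=1), 1e-12)
    mean_u *= scale[:, None]
    mean_s *= scale[:, None]

    theta = spec.genes["theta"].to_numpy()
    spliced = _sample_nb(rng, mean_s, theta)
    unspliced = _sample_nb(rng, mean_u, theta)

    # --- ERCC spike-ins: fixed expected counts, cell-independent ----------
    ercc_rng = np.random.default_rng(spec_hash(spec))
    ercc_profile = np.exp(ercc_rng.normal(0.0, 1.5, N_ERCC))
    ercc_profile *= spec.ercc_depth_fraction * depth / ercc_profile.sum()
    ercc_counts = _sample_nb(
        rng, np.broadcast_to(ercc_profile, (n_cells, N_ERCC)).copy(),
        np.full(N_ERCC, 30.0),
    )

    gene_ids = np.concatenate(
        [spec.genes["gene"].to_numpy(object),
         np.array([f"ERCC-{i:05d}" for i in range(N_ERCC)], dtype=object)]
    )
    ercc_flag = np.zeros(gene_ids.size, dtype=bool)
    ercc_flag[n_g:] = True
    zeros = np.zeros((n_cells, N_ERCC), dtype=np.int64)
    total = np.hstack([spliced + unspliced, ercc_counts])
    spl = np.hstack([spliced, ercc_counts])
    uns = np.hstack([unspliced, zeros])

    cell_ids = np.array([f"cell{i:04d}" for i in range(n_cells)], dtype=object)
    stage_edges = np.array([0.0, 0.8, 1.4, 2.0, np.inf])
    stage_names = np.array(["E12.5", "E13.5", "E14.5", "E16.5"])
    stages = stage_names[np.searchsorted(stage_edges, t_of, side="right") - 1]
    obs = pd.DataFrame(
        {
            "stage": stages,
            "plate": [f"P{1 + i // 384}" for i in range(n_cells)],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    container = CountContainer(
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        layers={
            "total": sp.csr_matrix(total),
            "spliced": sp.csr_matrix(spl),
            "unspliced": sp.csr_matrix(uns),
        },
        ercc=ercc_flag,
        obs=obs,
    )
    cells = pd.DataFrame(
        {
            "true_time": t_of,
            "segment": seg_of.astype(str),
            "bias_label": bias_label,
            "bias": bias,
            "path": [terms[p] for p in path_of],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    genes_truth = spec.genes.copy()
    genes_truth.attrs["terminal_segments"] = spec.terminal_segments
    truth = GroundTruth(cells=cells, genes=genes_truth,
                        low_quality=np.empty(0, dtype=int))
    return container, truth


def spec_hash(spec: LineageSpec) -> int:
    """Stable small-integer hash of the lineage used to pin the ERCC profile."""
    h = len(spec.genes) * 1009 + len(spec.segments) * 101 + N_ERCC
    return h % (2**31 - 1)


def make_qc_fixture(
    n_clean: int,
    n_fail: int,
    seed: int = 0,
    spec: LineageSpec | None = None,
) -> tuple[CountContainer, GroundTruth]:
    """Dataset with planted low-quality cells for exercising the QC filter.

    Clean cells strictly satisfy all three keep-conditions
    (transcripts > 5e4, detected genes > 3000, ERCC fraction < 25%); each of
    the ``n_fail`` planted cells violates at least one, with the three
    violation mechanisms (depth downscaling, gene masking, ERCC inflation)
    cycled so all are represented when n_fail >= 3.
    """
    if n_clean < 0 or n_fail < 0:
        raise ValueError("cell counts must be nonnegative")
    n = max(n_clean + n_fail, 50)
    if spec is None:
        spec = default_lineage()
    container, truth = simulate_dataset(spec, n_cells=n, depth=2.0e5, seed=seed)
    rng = np.random.default_rng(seed + 1)
    total = np.asarray(container.layers["total"].todense())
    ercc = container.ercc
    fail_idx = np.arange(n_clean, n_clean + n_fail)
    mechanisms = ["depth", "genes", "ercc"]
    for j, i in enumerate(fail_idx):
        mech = mechanisms[j % 3]
        row = total[i]
        if mech == "depth":
            cellular = row[~ercc]
            tot = cellular.sum()
            p = min(1.0, 2.0e4 / max(tot, 1))
            row[~ercc] = rng.binomial(cellular.astype(np.int64), p)
        elif mech == "genes":
            cellular_idx = np.where(~ercc)[0]
            order = np.argsort(row[cellular_idx])[::-1]
            drop = cellular_idx[order[2500:]]
            lost = row[drop].sum()
            row[drop] = 0
            kept_tot = row[~ercc].sum()
            if kept_tot <= 5.0e4:  # keep this a pure gene-count violation
                factor = int(np.ceil((5.0e4 + lost) / max(kept_tot, 1)))
                row[~ercc] *= factor
        else:  # ercc
            cellular_tot = row[~ercc].sum()
            target_ercc = int(np.ceil(0.8 * cellular_tot))  # fraction ~0.44
            cur = max(row[ercc].sum(), 1)
            row[ercc] = np.rint(row[ercc] * target_ercc / cur).astype(np.int64)
        total[i] = row
    # guard the clean block: strict transcript margin (vanishingly rare at
    # this depth, but the contract is strict)
    for i in range(n_clean):
        while total[i][~ercc].sum() <= 5.0e4:
            total[i][~ercc] *= 2
    keep = np.arange(n_clean + n_fail)
    out = CountContainer(
        cell_ids=container.cell_ids[keep],
        gene_ids=container.gene_ids,
        layers={"total": sp.csr_matrix(total[keep])},
        ercc=ercc,
        obs=container.obs.iloc[keep],
    )
    truth_cells = truth.cells.iloc[keep].copy()
    gt = GroundTruth(cells=truth_cells, genes=truth.genes,
                     low_quality=fail_idx.copy())
    return out, gt
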