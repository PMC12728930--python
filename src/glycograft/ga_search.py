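"""Genetic algorithm over the moiety's torsional degrees of freedom.

The chromosome is the torsion-angle vector of the grafted complex's
pose tree (two linkage torsions plus the moiety's internal rotatable
bonds), each gene on [-180, 180) degrees.  The receptor and the
carbohydrate core are rigid, so the search space is purely torsional
and the scaffold anchors the ligand.

Operators: tournament selection of size 2, uniform per-gene crossover,
Gaussian mutation wrapped to the circle, elitism of one.  The best-ever
fitness is therefore monotone non-increasing in the generation index,
and a fixed seed reproduces the trace bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grafting import GlycomimeticComplex, ReactiveCenter, ScaffoldComplex, graft
from .moiety_library import CappedMoiety, load_moiety_pdbqt
from .scoring import EnergyRecord, ScoringParameters, ScoringSession


@dataclass
class GAParams:
    population_size: int = 100
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.25
    mutation_sigma: float = 25.0      # degrees
    elitism_count: int = 1
    immigrant_fraction: float = 0.1   # fresh uniform individuals per generation
    convergence_window: int = 20
    convergence_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        for r in (self.crossover_rate, self.mutation_rate,
                  self.immigrant_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _wrap(t: np.ndarray) -> np.ndarray:
    return (t + 180.0) % 360.0 - 180.0


def randomize_torsions(pose: np.ndarray, seed: int) -> np.ndarray:
    """Uniform random torsions on [-180, 180), one per rotatable bond;
    deterministic per seed.  Used to remove starting-pose bias before
    screening."""
    pose = np.asarray(pose, dtype=float)
    rng = np.random.default_rng(seed)
    return rng.uniform(-180.0, 180.0, size=pose.shape)


@dataclass
class GATrace:
    best: list[float] = field(default_factory=list)
    mean: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"best": self.best, "mean": self.mean}


def optimize_pose(complex_: GlycomimeticComplex, params: GAParams,
                  scoring: ScoringParameters | None = None,
                  ) -> tuple[np.ndarray, EnergyRecord, GATrace]:
    """GA minimization of the VC score over the pose torsions.

    Returns (best pose, its energy record re-evaluated from scratch,
    per-generation best/mean trace).
    """
    scoring = scoring or ScoringParameters()
    session = ScoringSession(complex_, scoring)
    n = complex_.pose_tree.n_rot
    trace = GATrace()

    if n == 0:
        rec = session.score(None)
        trace.best.append(rec.total)
        trace.mean.append(rec.total)
        return np.zeros(0), rec, trace

    rng = np.random.default_rng(params.seed)
    pop = rng.uniform(-180.0, 180.0, size=(params.population_size, n))

    def fitness(pose: np.ndarray) -> float:
        try:
            return session.score(pose).total
        except Exception as exc:
            raise RuntimeError(f"scoring failed at generation {gen}") from exc

    gen = 0
    fits = np.array([fitness(p) for p in pop])
    best_idx = int(np.argmin(fits))
    best_pose = pop[best_idx].copy()
    best_fit = float(fits[best_idx])
    trace.best.append(best_fit)
    trace.mean.append(float(fits.mean()))

    for gen in range(1, params.generations + 1):
        new_pop = np.empty_like(pop)
        k = 0
        # elitism
        order = np.argsort(fits)
        for e in range(min(params.elitism_count, params.population_size)):
            new_pop[k] = pop[order[e]]
            k += 1
        # random immigrants keep exploring other basins of the
        # multimodal torsional landscape
        n_imm = int(params.immigrant_fraction * params.population_size)
        for _ in range(min(n_imm, params.population_size - k)):
            new_pop[k] = rng.uniform(-180.0, 180.0, size=n)
            k += 1
        while k < params.population_size:
            # tournament selection, size 2
            i1, i2 = rng.integers(0, params.population_size, size=2)
            p1 = pop[i1] if fits[i1] <= fits[i2] else pop[i2]
            i1, i2 = rng.integers(0, params.population_size, size=2)
            p2 = pop[i1] if fits[i1] <= fits[i2] else pop[i2]
            child = p1.copy()
            if rng.random() < params.crossover_rate:
                mask = rng.random(n) < 0.5
                child[mask] = p2[mask]
            mmask = rng.random(n) < params.mutation_rate
            if mmask.any():
                nm = int(mmask.sum())
                # coarse moves explore; 10x finer moves polish minima
                sigma = np.where(rng.random(nm) < 0.5,
                                 params.mutation_sigma,
                                 0.1 * params.mutation_sigma)
                child[mmask] = _wrap(child[mmask] + rng.normal(0.0, sigma))
            new_pop[k] = child
            k += 1
        pop = new_pop
        fits = np.array([fitness(p) for p in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_pose = pop[gen_best].copy()
        trace.best.append(best_fit)
        trace.mean.append(float(fits.mean()))
        w = params.convergence_window
        if w and len(trace.best) > w:
            if trace.best[-1 - w] - trace.best[-1] < params.convergence_tol:
                break

    record = session.score(best_pose)
    return best_pose, record, trace


def screen_library(scaffold_complex: ScaffoldComplex, center: ReactiveCenter,
                   library: str | Path | list[CappedMoiety],
                   params: GAParams,
                   scoring: ScoringParameters | None = None,
                   out_dir: str | Path | None = None) -> list[dict]:
    """Sequentially graft every library moiety onto the reactive center,
    GA-optimize each pose, and rank by best score (ascending).

    Per-moiety failures are recorded in the returned table and the run
    continues.  When `out_dir` is given, a pose PDB is written per
    moiety and a ranked TSV alongside.
    """
    from .analysis import write_complex_pdb

    if isinstance(library, (str, Path)):
        lib_dir = Path(library)
        entries = []
        for path in sorted(lib_dir.glob("*.pdbqt")):
            if path.name == "manifest.tsv":
                continue
            entries.append((path.stem, path))
    else:
        entries = [(m.identifier or f"moiety{k}", m) for k, m in enumerate(library)]
    if not entries:
        raise ValueError("moiety library is empty")

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for k, (ident, entry) in enumerate(entries):
        row = {"id": ident, "score": np.nan, "n_rot": -1, "pose_file": "",
               "status": "ok", "error": ""}
        try:
            moiety = entry if isinstance(entry, CappedMoiety) else \
                load_moiety_pdbqt(Path(entry).read_text())
            cx = graft(scaffold_complex, center, moiety)
            seed_k = (params.seed + 7919 * k) % (2**31 - 1)
            p = GAParams(**{**params.__dict__, "seed": seed_k})
            pose, rec, _trace = optimize_pose(cx, p, scoring)
            row["score"] = rec.total
            row["n_rot"] = cx.pose_tree.n_rot
            if out_dir is not None:
                from .scoring import apply_pose
                if cx.pose_tree.n_rot:
                    cx.ligand.set_coords(apply_pose(cx, pose))
                pose_path = out_dir / f"{ident}_pose.pdb"
                pose_path.write_text(write_complex_pdb(cx))
                row["pose_file"] = str(pose_path)
        except Exception as exc:
            row.update(status="failed", error=str(exc))
        rows.append(row)

    ok = sorted((r for r in rows if r["status"] == "ok"), key=lambda r: r["score"])
    failed = [r for r in rows if r["status"] != "ok"]
    ranked = ok + failed
    if out_dir is not None:
        lines = ["id\tscore\tn_rot\tpose_file\tstatus\terror"]
        for r in ranked:
            lines.append(f"{r['id']}\t{r['score']:.6f}\t{r['n_rot']}\t"
                         f"{r['pose_file']}\t{r['status']}\t{r['error']}")
        (out_dir / "ranking.tsv").write_text("\n".join(lines) + "\n")
    return ranked
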