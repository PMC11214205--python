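"""Divergent-selection breeding-scheme simulator.

Two pig lines (HPM and HRT) are bred for three generations from a common
founder population, selecting in each line on the relative abundance of the
keystone taxa of its target enterotype (Prevotella/Mitsuokella for HPM,
Treponema/Ruminococcus for HRT).  The enterotype label itself follows a
liability-threshold model: an animal is PM when its liability phenotype
exceeds a threshold fixed at the base-population median.  Taxon abundances,
liability and post-weaning growth (ADG) are linked through a one-factor
genetic-correlation structure (positive loadings for the PM-side traits,
negative for the RT side), so selection on taxon phenotypes drags the
enterotype and growth as correlated responses.

Quantities simulated per animal: breeding values (multivariate normal,
offspring = midparent + Mendelian sampling scaled by parental inbreeding),
a common-litter deviation, batch and sex fixed effects, and an independent
residual per trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .reml import precorrect_batch

logger = logging.getLogger(__name__)

TRAITS = ("prevotella", "mitsuokella", "treponema", "ruminococcus", "liability", "adg")

LINE_CRITERIA = {
    "HPM": ("prevotella", "mitsuokella"),
    "HRT": ("treponema", "ruminococcus"),
}


@dataclass
class BreedingScheme:
    """The reference design of the selection experiment."""

    n_founder_sires: int = 30
    n_founder_dams: int = 30
    n_sires: int = 6
    n_dams: int = 30
    n_litters: int = 30
    g0_total: int = 316
    # per-generation (HPM, HRT) phenotyped offspring counts
    line_totals: dict = field(default_factory=lambda: {1: (133, 139), 2: (114, 114), 3: (126, 125)})
    n_generations: int = 3
    one_boar_per_sire: bool = True
    g1_litter_basis_females: bool = True

    @property
    def total_phenotyped(self) -> int:
        return self.g0_total + sum(a + b for a, b in self.line_totals.values())


@dataclass
class GeneticArchitecture:
    """Per-trait heritabilities, litter fractions and the genetic-correlation
    structure.

    ``loadings`` are the traits' loadings on a single latent "PM axis":
    rG(i, j) = loading_i * loading_j for i != j, which is positive within an
    enterotype, negative between enterotypes, and positive-semidefinite by
    construction.  Defaults: taxa and liability heritability 0.3, growth 0.2,
    litter fraction 0.05; |rG| between opposite primary taxa > 0.9, growth
    correlated with taxa at |rG| in the 0.32-0.52 band.
    """

    h2: dict = field(default_factory=lambda: {
        "prevotella": 0.3, "mitsuokella": 0.3, "treponema": 0.3,
        "ruminococcus": 0.3, "liability": 0.3, "adg": 0.2,
    })
    c2: dict = field(default_factory=lambda: {t: 0.05 for t in TRAITS})
    loadings: dict = field(default_factory=lambda: {
        "prevotella": 0.95, "mitsuokella": 0.75, "treponema": -0.95,
        "ruminococcus": -0.75, "liability": 0.95, "adg": 0.5,
    })
    sigma_p: dict = field(default_factory=lambda: {t: 1.0 for t in TRAITS})
    sex_effect: float = 0.1      # male minus female, in phenotypic SD units
    batch_sd: float = 0.3        # SD of batch effects, phenotypic SD units
    n_batches_per_gen: int = 4
    threshold: float | None = None  # None: G0 median liability

    def rg_matrix(self) -> np.ndarray:
        lam = np.array([self.loadings[t] for t in TRAITS])
        if np.any(np.abs(lam) > 1):
            raise ValueError("loadings must lie in [-1, 1]")
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        return R

    def sigma_a(self) -> np.ndarray:
        sa = np.array([np.sqrt(self.h2[t]) * self.sigma_p[t] for t in TRAITS])
        S = self.rg_matrix() * np.outer(sa, sa)
        eig = np.linalg.eigvalsh(S)
        if eig.min() < -1e-10:
            raise ValueError("genetic covariance matrix is not positive semidefinite")
        return S


@dataclass
class SimulatedPopulation:
    pedigree: Pedigree
    data: pd.DataFrame        # one row per phenotyped animal
    threshold: float
    scheme: BreedingScheme
    architecture: GeneticArchitecture


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------


def select_sires(candidates: pd.DataFrame, primary: str, secondary: str, n_select: int = 6) -> list[str]:
    """Two-stage intra-sire-family male selection.

    Within each sire family, rank males on the (batch-precorrected) primary
    trait, keep the top three (or all if fewer), and among them pick the one
    with the highest secondary-trait value.  Across the per-family picks,
    keep the ``n_select`` with the highest primary values (one boar per
    sire).  Ties break by animal id.
    """
    fams = candidates.groupby("sire", sort=True)
    picks = []
    for _, fam in fams:
        fam = fam.sort_values([primary, "animal"], ascending=[False, True])
        top = fam.head(3)
        best = top.sort_values([secondary, primary, "animal"], ascending=[False, False, True]).iloc[0]
        picks.append(best)
    if len(picks) < n_select:
        raise ValueError(f"only {len(picks)} sire families with male candidates; need {n_select}")
    picks = pd.DataFrame(picks).sort_values([primary, "animal"], ascending=[False, True])
    return list(picks.head(n_select)["animal"])


def select_dams(
    candidates: pd.DataFrame,
    primary: str,
    n_select: int = 30,
    litter_basis: bool = False,
    max_per_litter: int = 2,
) -> list[str]:
    """Female selection: litter-capped greedy (first selection round) or mass.

    With ``litter_basis`` (used for G0 -> G1 only), the best female of each
    litter is taken first (litters in descending order of their best female),
    then second-best females, with at most ``max_per_litter`` per litter.
    Otherwise the global top ``n_select`` on the primary trait are taken.
    """
    if len(candidates) < n_select:
        raise ValueError(f"only {len(candidates)} female candidates; need {n_select}")
    ranked = candidates.sort_values([primary, "animal"], ascending=[False, True])
    if not litter_basis:
        return list(ranked.head(n_select)["animal"])
    chosen: list[str] = []
    for round_rank in range(max_per_litter):
        pool = ranked.groupby("litter", sort=False).nth(round_rank)
        pool = pool.sort_values([primary, "animal"], ascending=[False, True])
        for _, row in pool.iterrows():
            if len(chosen) >= n_select:
                return chosen
            chosen.append(row["animal"])
    if len(chosen) < n_select:
        raise ValueError(
            f"litter-basis selection exhausted at {len(chosen)} females "
            f"(cap {max_per_litter} per litter); need {n_select}"
        )
    return chosen


def mate(
    sires: list[str],
    dams: list[str],
    parents: dict[str, tuple[str, str]],
    seed: int = 0,
    max_tries: int = 200,
) -> list[tuple[str, str]]:
    """Balanced sire-dam assignment avoiding fullsib/halfsib pairs.

    Each sire receives ``len(dams) // len(sires)`` dams; a pair is forbidden
    when the two animals share a sire or a dam.  Assignment is randomized
    under ``seed`` and resolved by rejection with backtracking.
    """
    if len(dams) % len(sires):
        raise ValueError("number of dams must be a multiple of the number of sires")
    per_sire = len(dams) // len(sires)
    rng = np.random.default_rng(seed)

    def compatible(a: str, b: str) -> bool:
        pa, pb = parents.get(a, ("0", "0")), parents.get(b, ("0", "0"))
        shared = {p for p in pa if p != "0"} & {p for p in pb if p != "0"}
        return not shared

    forbidden_counts = {
        s: sum(not compatible(s, d) for d in dams) for s in sires
    }
    for _ in range(max_tries):
        order = list(rng.permutation(dams))
        # most-constrained sires pick first
        sire_order = sorted(sires, key=lambda s: -forbidden_counts[s])
        assignment: dict[str, list[str]] = {s: [] for s in sires}
        ok = _assign(sire_order, order, assignment, per_sire, compatible)
        if ok:
            pairs = [(s, d) for s in sires for d in assignment[s]]
            return pairs
    conflicts = {s: [d for d in dams if not compatible(s, d)] for s in sires}
    raise ValueError(f"no feasible balanced mating found; conflicts: {conflicts}")


def _assign(sires, dams, assignment, per_sire, compatible):
    if not dams:
        return True
    d = dams[0]
    for s in sires:
        if len(assignment[s]) < per_sire and compatible(s, d):
            assignment[s].append(d)
            if _assign(sires, dams[1:], assignment, per_sire, compatible):
                return True
            assignment[s].pop()
    return False


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


class _PopState:
    """Growing pedigree with incremental relationship bookkeeping."""

    def __init__(self, capacity: int, n_traits: int, rng: np.random.Generator):
        self.A = np.zeros((capacity, capacity))
        self.bv = np.zeros((capacity, n_traits))
        self.ids: list[str] = []
        self.index: dict[str, int] = {}
        self.rng = rng
        self.records: list[dict] = []
        self._factor: np.ndarray | None = None

    def _draw(self, Sa: np.ndarray, scale: float = 1.0) -> np.ndarray:
        # PSD square root computed once (handles zero-variance traits)
        if self._factor is None:
            w, V = np.linalg.eigh(Sa)
            self._factor = V * np.sqrt(np.maximum(w, 0.0))
        z = self.rng.standard_normal(Sa.shape[0])
        return np.sqrt(scale) * (self._factor @ z)

    def add(self, animal: str, sire: str | None, dam: str | None, Sa: np.ndarray, **meta) -> int:
        i = len(self.ids)
        if sire is None:
            self.A[i, i] = 1.0
            self.bv[i] = self._draw(Sa)
        else:
            s, d = self.index[sire], self.index[dam]
            row = 0.5 * (self.A[s, :i] + self.A[d, :i])
            self.A[i, :i] = row
            self.A[:i, i] = row
            self.A[i, i] = 1.0 + 0.5 * self.A[s, d]
            f_s, f_d = self.A[s, s] - 1.0, self.A[d, d] - 1.0
            k = 0.5 * (1.0 - 0.5 * (f_s + f_d))
            self.bv[i] = 0.5 * (self.bv[s] + self.bv[d]) + self._draw(Sa, scale=k)
        self.ids.append(animal)
        self.index[animal] = i
        self.records.append({"animal": animal, "sire": sire or "0", "dam": dam or "0", **meta})
        return i


def simulate_population(
    scheme: BreedingScheme | None = None,
    arch: GeneticArchitecture | None = None,
    seed: int = 0,
    selection: bool = True,
) -> SimulatedPopulation:
    """Simulate the full multi-generation divergent-selection experiment.

    With ``selection=False`` parents are drawn at random under the same
    design constraints (one boar per sire family, 30 dams, balanced matings),
    which gives a random-mating population on the study pedigree structure
    for parameter-recovery analyses.
    """
    scheme = scheme or BreedingScheme()
    arch = arch or GeneticArchitecture()
    rng = np.random.default_rng(seed)
    Sa = arch.sigma_a()
    nt = len(TRAITS)
    sp = np.array([arch.sigma_p[t] for t in TRAITS])
    sc = np.sqrt(np.array([arch.c2[t] for t in TRAITS])) * sp
    se = np.sqrt(np.array([1.0 - arch.h2[t] - arch.c2[t] for t in TRAITS])) * sp
    if np.any(se < 0):
        raise ValueError("h2 + c2 must be <= 1 for every trait")

    capacity = scheme.n_founder_sires + scheme.n_founder_dams + scheme.total_phenotyped + 8
    pop = _PopState(capacity, nt, rng)

    founder_sires = [f"FS{i:03d}" for i in range(scheme.n_founder_sires)]
    founder_dams = [f"FD{i:03d}" for i in range(scheme.n_founder_dams)]
    for a in founder_sires:
        pop.add(a, None, None, Sa, generation="F", line="", sex="M", litter="", batch="")
    for a in founder_dams:
        pop.add(a, None, None, Sa, generation="F", line="", sex="F", litter="", batch="")

    pheno_rows: list[dict] = []

    def gen_batches(gen_label):
        """Batches are rearing groups shared by both lines within a generation."""
        batches = [f"{gen_label}b{j}" for j in range(arch.n_batches_per_gen)]
        return batches, {b: rng.normal(0.0, arch.batch_sd * sp) for b in batches}

    def make_offspring(pairs, totals, gen_label, line_label, counter, batches, batch_eff):
        """Produce `totals` phenotyped piglets from the mating pairs."""
        sizes = rng.multinomial(totals, np.full(len(pairs), 1.0 / len(pairs)))
        rows = []
        for (sire, dam), size in zip(pairs, sizes):
            litter_id = f"L{gen_label}{line_label}_{sire}x{dam}"
            litter_dev = rng.normal(0.0, sc)
            batch = batches[int(rng.integers(len(batches)))]
            for _ in range(size):
                animal = f"{gen_label}{line_label}_{counter[0]:04d}"
                counter[0] += 1
                sex = "M" if rng.random() < 0.5 else "F"
                i = pop.add(animal, sire, dam, Sa, generation=gen_label,
                            line=line_label, sex=sex, litter=litter_id, batch=batch)
                resid = rng.normal(0.0, se)
                sex_eff = arch.sex_effect * sp if sex == "M" else np.zeros(nt)
                phen = pop.bv[i] + litter_dev + batch_eff[batch] + sex_eff + resid
                row = {"animal": animal, "sire": sire, "dam": dam, "generation": gen_label,
                       "line": line_label, "sex": sex, "litter": litter_id, "batch": batch}
                row.update({t: phen[j] for j, t in enumerate(TRAITS)})
                row.update({f"bv_{t}": pop.bv[i][j] for j, t in enumerate(TRAITS)})
                rows.append(row)
        return rows

    # --- G0: 30 founder pairs, one litter each ---------------------------
    g0_pairs = list(zip(founder_sires, founder_dams))
    counter = [0]
    b0, be0 = gen_batches("G0")
    g0_rows = make_offspring(g0_pairs, scheme.g0_total, "G0", "", counter, b0, be0)
    pheno_rows.extend(g0_rows)
    g0 = pd.DataFrame(g0_rows)
    threshold = arch.threshold if arch.threshold is not None else float(g0["liability"].median())

    # --- successive selected generations ---------------------------------
    current = {"HPM": g0, "HRT": g0}
    taken_males: set[str] = set()
    taken_females: set[str] = set()
    parents_map = lambda: {r["animal"]: (r["sire"], r["dam"]) for r in pop.records}

    for gen in range(1, scheme.n_generations + 1):
        next_current = {}
        bg, beg = gen_batches(f"G{gen}")
        for li, line in enumerate(("HPM", "HRT")):
            cand = current[line].copy()
            if gen == 1:
                cand = cand[~cand["animal"].isin(taken_males | taken_females)]
            primary, secondary = LINE_CRITERIA[line]
            # selection criterion: batch-precorrected abundances
            for tr in (primary, secondary):
                cand[f"crit_{tr}"] = precorrect_batch(cand, tr).to_numpy()
            males = cand[cand["sex"] == "M"].rename(
                columns={f"crit_{primary}": "p_", f"crit_{secondary}": "s_"})
            females = cand[cand["sex"] == "F"].rename(columns={f"crit_{primary}": "p_"})
            if selection:
                sires = select_sires(males, "p_", "s_", scheme.n_sires)
                dams = select_dams(
                    females, "p_", scheme.n_dams,
                    litter_basis=scheme.g1_litter_basis_females and gen == 1,
                )
            else:
                sires = _random_one_per_family(males, scheme.n_sires, rng)
                dams = list(females.sample(n=scheme.n_dams, random_state=int(rng.integers(2**31)))["animal"])
            taken_males.update(sires)
            taken_females.update(dams)
            pairs = mate(sires, dams, parents_map(), seed=int(rng.integers(2**31)))
            total = scheme.line_totals[gen][li]
            rows = make_offspring(pairs, total, f"G{gen}", line, counter, bg, beg)
            pheno_rows.extend(rows)
            next_current[line] = pd.DataFrame(rows)
        current = next_current

    data = pd.DataFrame(pheno_rows)
    data["enterotype"] = np.where(data["liability"] > threshold, "PM", "RT")
    data["enterotype01"] = (data["enterotype"] == "PM").astype(float)
    ped = Pedigree(pd.DataFrame(pop.records))
    return SimulatedPopulation(ped, data, threshold, scheme, arch)


def _random_one_per_family(males: pd.DataFrame, n_select: int, rng) -> list[str]:
    picks = []
    for _, fam in males.groupby("sire", sort=True):
        picks.append(fam.sample(n=1, random_state=int(rng.integers(2**31)))["animal"].iloc[0])
    if len(picks) < n_select:
        raise ValueError(f"only {len(picks)} sire families with males; need {n_select}")
    rng.shuffle(picks)
    return picks[:n_select]


# ---------------------------------------------------------------------------
# replicate runner and small oracles
# ---------------------------------------------------------------------------


def run_scheme(
    scheme: BreedingScheme | None = None,
    arch: GeneticArchitecture | None = None,
    n_replicates: int = 50,
    seed: int = 0,
    selection: bool = True,
    return_replicates: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate the breeding scheme; per line x generation trajectory summary.

    Returns mean enterotype prevalence (percent), mean selected-taxon
    phenotypes and mean growth per line and generation, with Monte-Carlo
    standard errors across replicates.  With ``return_replicates`` the
    per-replicate table is returned alongside the summary.
    """
    scheme = scheme or BreedingScheme()
    arch = arch or GeneticArchitecture()
    rng = np.random.default_rng(seed)
    per_rep = []
    for rep in range(n_replicates):
        pop = simulate_population(scheme, arch, seed=int(rng.integers(2**31)), selection=selection)
        d = pop.data
        d = d.assign(line_g0=d["line"].where(d["line"] != "", "G0"))
        grp = d.groupby(["generation", "line_g0"])
        summary = grp.agg(
            n=("animal", "size"),
            pm_prevalence=("enterotype01", lambda x: 100.0 * x.mean()),
            prevotella=("prevotella", "mean"),
            mitsuokella=("mitsuokella", "mean"),
            treponema=("treponema", "mean"),
            ruminococcus=("ruminococcus", "mean"),
            adg=("adg", "mean"),
        ).reset_index()
        summary["rt_prevalence"] = 100.0 - summary["pm_prevalence"]
        summary["replicate"] = rep
        per_rep.append(summary)
    allreps = pd.concat(per_rep, ignore_index=True)
    out = (
        allreps.groupby(["generation", "line_g0"])
        .agg(**{
            "n": ("n", "mean"),
            **{c: (c, "mean") for c in ("pm_prevalence", "rt_prevalence", "prevotella",
                                        "mitsuokella", "treponema", "ruminococcus", "adg")},
            "pm_prevalence_se": ("pm_prevalence", lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0),
        })
        .reset_index()
        .rename(columns={"line_g0": "line"})
    )
    if return_replicates:
        return out, allreps.rename(columns={"line_g0": "line"})
    return out


def simulate_mass_selection(
    n_offspring: int = 4000,
    h2: float = 0.3,
    select_frac: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """One generation of mass selection without family structure.

    Parents are unrelated; the top ``select_frac`` of each sex by phenotype
    are mated at random.  Returns ``(S, R)``: the selection differential and
    the realized response (offspring phenotype mean), both relative to the
    base-population mean, for checking against the breeder's equation
    R = h2 * S.
    """
    rng = np.random.default_rng(seed)
    n = n_offspring
    bv = rng.normal(0.0, np.sqrt(h2), size=n)
    phen = bv + rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
    sex = rng.random(n) < 0.5
    selected = []
    for mask in (sex, ~sex):
        idx = np.nonzero(mask)[0]
        k = max(int(round(select_frac * len(idx))), 1)
        top = idx[np.argsort(phen[idx])[::-1][:k]]
        selected.append(top)
    males, females = selected
    S = float(phen[np.concatenate([males, females])].mean() - phen.mean())
    sires = rng.choice(males, size=n)
    dams = rng.choice(females, size=n)
    bv_off = 0.5 * (bv[sires] + bv[dams]) + rng.normal(0.0, np.sqrt(0.5 * h2), size=n)
    phen_off = bv_off + rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
    R = float(phen_off.mean() - phen.mean())
    return S, R
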