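"""Forward simulation of an island pedigree with binomial extra-pair paternity.

The generator emulates a small, open, socially monogamous island population:
founder pairs establish the population, roughly one parentless immigrant
arrives per year, adults survive between years and re-pair, and each social
pair rears one to a few broods of 1-4 offspring per year.  Each brood's
number of extra-pair offspring is binomial with a logit-scale liability

    eta = intercept + beta_year (year - baseline) + beta_age age_m
          + g_f q_f + g_m q_m + a_f(female) + a_m(male)
          + pe_f + pe_m + pair + year + residual,

where (a_f, a_m) are cross-sex breeding values inherited down the pedigree
under the infinitesimal model (parental midpoint plus Mendelian-sampling
noise with covariance 0.5 G (1 - (F_dam + F_sire)/2)), q is the immigrant
genetic-group coefficient, and the total additive genetic value satisfies
u = a + g q exactly.  Extra-pair offspring receive a random contemporary
extra-pair sire, so the realised pedigree is the *genetic* pedigree, as in
populations with molecular parentage assignment.

Default parameter values are the estimated study conditions of the
motivating island system (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, assign_genetic_groups, compute_q

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "SimulationError",
    "simulate_dataset",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes",
]


class SimulationError(RuntimeError):
    pass


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameters; defaults are the study conditions.

    Latent-scale truth (intercept, slopes, group effects, (co)variances)
    defaults to the fitted values of the motivating analysis; demographic
    knobs are chosen to yield ~35-45 social pairs and ~1,200 broods over 24
    breeding years, with ~1 immigrant per year.
    """

    n_years: int = 24
    n_founder_pairs: int = 12
    immigrants_per_year: float = 1.0
    # Poisson mean before >=1 truncation; 0.9 gives ~1.5 broods/pair/year
    mean_broods_per_pair: float = 0.9
    brood_size_min: int = 1
    brood_size_max: int = 4
    adult_survival: float = 0.6
    recruit_prob: float = 0.3
    max_adults: int = 90
    # latent-scale truth
    intercept: float = -0.67
    beta_year: float = 0.05
    beta_age: float = -0.19
    g_f: float = -1.17
    g_m: float = -1.55
    var_af: float = 1.26
    var_am: float = 0.47
    cov_afam: float = -0.37
    var_pe_f: float = 0.1
    var_pe_m: float = 0.1
    var_pair: float = 0.1
    var_year: float = 0.1
    var_residual: float = 3.58
    seed: int = 0

    @property
    def G(self) -> np.ndarray:
        return np.array([[self.var_af, self.cov_afam], [self.cov_afam, self.var_am]])

    def validate(self) -> None:
        if self.brood_size_min < 1 or self.brood_size_max < self.brood_size_min:
            raise ValueError("brood sizes must satisfy 1 <= min <= max")
        for name in ("var_af", "var_am", "var_pe_f", "var_pe_m", "var_pair", "var_year", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.cov_afam**2 > self.var_af * self.var_am + 1e-12:
            raise ValueError("G is not positive semidefinite (cov^2 > var_af * var_am)")
        if self.immigrants_per_year < 0:
            raise ValueError("immigrants_per_year must be nonnegative")
        if self.mean_broods_per_pair <= 0:
            raise ValueError("mean_broods_per_pair must be positive")


@dataclasses.dataclass
class SimulatedDataset:
    """Pedigree, brood phenotypes, and the full latent truth."""

    pedigree: Pedigree
    broods: pd.DataFrame
    truth: pd.DataFrame  # per individual: sex, q, a_f, a_m, u_f, u_m, pe_f, pe_m, F
    effects: dict  # year_effects, pair_effects, per-brood residuals
    config: SimulationConfig


def _chol_psd(G: np.ndarray) -> np.ndarray:
    # tolerate a singular (perfectly correlated or zero-variance) G
    w, v = np.linalg.eigh(G)
    if w.min() < -1e-10:
        raise ValueError("G must be positive semidefinite")
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _trunc_poisson_ge1(rng: np.random.Generator, mean: float) -> int:
    while True:
        k = rng.poisson(mean)
        if k >= 1:
            return int(k)


class _Engine:
    """One forward pass over years; kinship is maintained among breeders."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        self.rng = rng
        self.L = _chol_psd(cfg.G)
        self.records: list[dict] = []  # pedigree rows
        self.a = []  # (a_f, a_m) per individual
        self.pe = []  # (pe_f, pe_m)
        self.q: list[float] = []
        self.F: list[float] = []
        self.kin_index: dict[int, int] = {}  # individual -> row of kinship matrix
        cap = 4 * cfg.max_adults * cfg.n_years // 8 + 4 * cfg.n_founder_pairs + 64
        self.kin = np.zeros((cap, cap))
        self.broods: list[dict] = []
        self.year_effects: dict[int, float] = {}
        self.pair_effects: dict[tuple[int, int], float] = {}
        self.residuals: list[float] = []

    # -- individuals ---------------------------------------------------
    def _new_individual(self, dam, sire, sex, cohort, immigrant, q, a, F) -> int:
        idx = len(self.records)
        self.records.append(
            dict(id=str(idx + 1), dam=None if dam is None else str(dam + 1),
                 sire=None if sire is None else str(sire + 1),
                 sex=sex, cohort=cohort, immigrant=immigrant)
        )
        self.a.append(a)
        self.pe.append(self.rng.normal(0.0, [np.sqrt(self.cfg.var_pe_f), np.sqrt(self.cfg.var_pe_m)]))
        self.q.append(q)
        self.F.append(F)
        return idx

    def _register_breeder(self, idx: int) -> None:
        """Add a kinship row for an individual entering the breeding pool."""
        if idx in self.kin_index:
            return
        k = len(self.kin_index)
        if k >= self.kin.shape[0]:
            grown = np.zeros((2 * self.kin.shape[0], 2 * self.kin.shape[0]))
            grown[: self.kin.shape[0], : self.kin.shape[0]] = self.kin
            self.kin = grown
        rec = self.records[idx]
        d = None if rec["dam"] is None else int(rec["dam"]) - 1
        s = None if rec["sire"] is None else int(rec["sire"]) - 1
        row = np.zeros(k)
        for p in (d, s):
            if p is not None and p in self.kin_index:
                row += 0.5 * self.kin[self.kin_index[p], :k]
        self.kin[k, :k] = row
        self.kin[:k, k] = row
        self.kin[k, k] = 0.5 * (1.0 + self.F[idx])
        self.kin_index[idx] = k

    def _parent_kinship(self, d: int, s: int) -> float:
        return float(self.kin[self.kin_index[d], self.kin_index[s]])

    def _founder(self, sex: str, cohort: int, immigrant: bool) -> int:
        a = self.L @ self.rng.standard_normal(2)
        q = 1.0 if immigrant else 0.0
        idx = self._new_individual(None, None, sex, cohort, immigrant, q, a, 0.0)
        self._register_breeder(idx)
        return idx

    def _offspring(self, dam: int, sire: int, sex: str, cohort: int) -> int:
        f = self._parent_kinship(dam, sire)
        scale = 0.5 * (1.0 - 0.5 * (self.F[dam] + self.F[sire]))
        mid = 0.5 * (self.a[dam] + self.a[sire])
        a = mid + np.sqrt(max(scale, 0.0)) * (self.L @ self.rng.standard_normal(2))
        q = 0.5 * (self.q[dam] + self.q[sire])
        return self._new_individual(dam, sire, sex, cohort, False, q, a, f)

    # -- main loop -----------------------------------------------------
    def run(self) -> None:
        cfg, rng = self.cfg, self.rng
        females: list[int] = []
        males: list[int] = []
        for _ in range(cfg.n_founder_pairs):
            females.append(self._founder("F", 0, False))
            males.append(self._founder("M", 0, False))
        juveniles: list[int] = []
        for year in range(1, cfg.n_years + 1):
            n_imm = rng.poisson(cfg.immigrants_per_year)
            for _ in range(n_imm):
                sex = "F" if rng.random() < 0.5 else "M"
                idx = self._founder(sex, year - 1, True)
                (females if sex == "F" else males).append(idx)
            # recruit last year's juveniles
            for idx in juveniles:
                self._register_breeder(idx)
                (females if self.records[idx]["sex"] == "F" else males).append(idx)
            juveniles = []
            # density cap
            adults = females + males
            if len(adults) > cfg.max_adults:
                keep = set(rng.choice(adults, size=cfg.max_adults, replace=False).tolist())
                females = [i for i in females if i in keep]
                males = [i for i in males if i in keep]
            if not females or not males:
                raise SimulationError(
                    f"population went extinct in year {year}; "
                    "increase n_founder_pairs or survival/recruitment"
                )
            rng.shuffle(females)
            rng.shuffle(males)
            pairs = list(zip(females, males))
            self.year_effects[year] = rng.normal(0.0, np.sqrt(cfg.var_year))
            for fem, mal in pairs:
                key = (fem, mal)
                if key not in self.pair_effects:
                    self.pair_effects[key] = rng.normal(0.0, np.sqrt(cfg.var_pair))
                n_broods = _trunc_poisson_ge1(rng, cfg.mean_broods_per_pair)
                for _ in range(n_broods):
                    self._brood(fem, mal, year, pairs, juveniles)
            # survival
            females = [i for i in females if rng.random() < cfg.adult_survival]
            males = [i for i in males if rng.random() < cfg.adult_survival]
            survivors_juv = []
            for idx in juveniles:
                if rng.random() < cfg.recruit_prob:
                    survivors_juv.append(idx)
            juveniles = survivors_juv
        if not self.broods:
            raise SimulationError("simulation produced no broods")

    def _brood(self, fem: int, mal: int, year: int, pairs, juveniles) -> None:
        cfg, rng = self.cfg, self.rng
        size = int(rng.integers(cfg.brood_size_min, cfg.brood_size_max + 1))
        male_age = year - self.records[mal]["cohort"]
        resid = rng.normal(0.0, np.sqrt(cfg.var_residual))
        eta = (
            cfg.intercept
            + cfg.beta_year * (year - 1)
            + cfg.beta_age * male_age
            + cfg.g_f * self.q[fem]
            + cfg.g_m * self.q[mal]
            + self.a[fem][0]
            + self.a[mal][1]
            + self.pe[fem][0]
            + self.pe[mal][1]
            + self.pair_effects[(fem, mal)]
            + self.year_effects[year]
            + resid
        )
        p = 1.0 / (1.0 + np.exp(-eta))
        n_epo = int(rng.binomial(size, p))
        other_males = [m for _, m in pairs if m != mal]
        if not other_males:
            n_epo = 0  # no extra-pair sire available
        self.residuals.append(resid)
        self.broods.append(
            dict(
                brood_id=f"b{len(self.broods) + 1}",
                year=year,
                female_id=str(fem + 1),
                male_id=str(mal + 1),
                male_age=int(male_age),
                n_offspring=size,
                n_epo=n_epo,
            )
        )
        ep_slots = set(rng.choice(size, size=n_epo, replace=False).tolist()) if n_epo else set()
        for slot in range(size):
            sire = int(rng.choice(other_males)) if slot in ep_slots else mal
            sex = "F" if rng.random() < 0.5 else "M"
            juveniles.append(self._offspring(fem, sire, sex, year))


def simulate_dataset(cfg: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Run the forward engine; pedigree, broods and truth are consistent."""
    cfg = dataclasses.replace(cfg) if cfg is not None else SimulationConfig()
    if seed is not None:
        cfg.seed = seed
    rng = np.random.default_rng(cfg.seed)
    eng = _Engine(cfg, rng)
    eng.run()
    ped = Pedigree(pd.DataFrame(eng.records))
    a = np.array(eng.a)
    pe = np.array(eng.pe)
    q = np.array(eng.q)
    truth = pd.DataFrame(
        {
            "id": [r["id"] for r in eng.records],
            "sex": [r["sex"] for r in eng.records],
            "q": q,
            "a_f": a[:, 0],
            "a_m": a[:, 1],
            "u_f": a[:, 0] + cfg.g_f * q,
            "u_m": a[:, 1] + cfg.g_m * q,
            "pe_f": pe[:, 0],
            "pe_m": pe[:, 1],
            "F": eng.F,
        }
    ).set_index("id")
    broods = pd.DataFrame(eng.broods)
    effects = dict(
        year_effects=dict(eng.year_effects),
        pair_effects={
            (str(f + 1), str(m + 1)): v for (f, m), v in eng.pair_effects.items()
        },
        residuals=np.array(eng.residuals),
    )
    return SimulatedDataset(pedigree=ped, broods=broods, truth=truth, effects=effects, config=cfg)


def simulate_pedigree(cfg: SimulationConfig | None = None, seed: int | None = None) -> Pedigree:
    """Convenience wrapper returning only the pedigree of a full engine run."""
    return simulate_dataset(cfg, seed=seed).pedigree


def simulate_breeding_values(
    ped: Pedigree,
    cfg: SimulationConfig,
    seed: int | None = None,
    cutoff_year: int | None = None,
) -> pd.DataFrame:
    """Gene-drop fresh breeding values down a fixed pedigree.

    Founders (including immigrants) draw (a_f, a_m) from N(0, G); the
    immigrant group-mean shift is carried entirely by g q in u, never by a.
    Non-founders draw the parental midpoint plus Mendelian-sampling noise
    with covariance 0.5 G (1 - (F_dam + F_sire)/2).  Returns a frame with
    a_f, a_m, q, u_f, u_m indexed by id.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    L = _chol_psd(cfg.G)
    dam, sire = ped.parent_indices()
    from .pedigree import inbreeding_coefficients

    F = inbreeding_coefficients(ped).to_numpy()
    n = ped.n
    a = np.zeros((n, 2))
    for i in range(n):
        d, s = dam[i], sire[i]
        if d < 0 and s < 0:
            a[i] = L @ rng.standard_normal(2)
        else:
            # a missing single parent is treated as an unrelated group member
            mid = np.zeros(2)
            f_d = F[d] if d >= 0 else 0.0
            f_s = F[s] if s >= 0 else 0.0
            if d >= 0:
                mid += 0.5 * a[d]
            if s >= 0:
                mid += 0.5 * a[s]
            scale = 0.5 * (1.0 - 0.5 * (f_d + f_s))
            a[i] = mid + np.sqrt(max(scale, 0.0)) * (L @ rng.standard_normal(2))
    groups = assign_genetic_groups(ped, cutoff_year)
    q = compute_q(ped, groups).q.to_numpy()
    return pd.DataFrame(
        {
            "a_f": a[:, 0],
            "a_m": a[:, 1],
            "q": q,
            "u_f": a[:, 0] + cfg.g_f * q,
            "u_m": a[:, 1] + cfg.g_m * q,
        },
        index=pd.Index(ped.ids, name="id"),
    )


def simulate_phenotypes(
    broods_template: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Redraw binomial phenotypes on a fixed brood skeleton given truth.

    ``broods_template`` supplies (brood_id, year, female_id, male_id,
    male_age, n_offspring); ``truth`` supplies a_f, a_m, q per individual.
    Permanent-environment, pair, year, and residual effects are drawn
    fresh, so repeated calls give independent replicate datasets with the
    same pedigree and observation structure.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    base_year = int(broods_template["year"].min())
    females = broods_template["female_id"].astype(str)
    males = broods_template["male_id"].astype(str)
    pe_f = pd.Series(
        rng.normal(0.0, np.sqrt(cfg.var_pe_f), truth.shape[0]), index=truth.index
    )
    pe_m = pd.Series(
        rng.normal(0.0, np.sqrt(cfg.var_pe_m), truth.shape[0]), index=truth.index
    )
    years = sorted(broods_template["year"].unique())
    yr_eff = {y: rng.normal(0.0, np.sqrt(cfg.var_year)) for y in years}
    pair_eff: dict[tuple[str, str], float] = {}
    out = broods_template.copy().reset_index(drop=True)
    n_epo = np.zeros(len(out), dtype=int)
    for b, row in out.iterrows():
        f, m = str(row["female_id"]), str(row["male_id"])
        key = (f, m)
        if key not in pair_eff:
            pair_eff[key] = rng.normal(0.0, np.sqrt(cfg.var_pair))
        eta = (
            cfg.intercept
            + cfg.beta_year * (row["year"] - base_year)
            + cfg.beta_age * row["male_age"]
            + cfg.g_f * truth.loc[f, "q"]
            + cfg.g_m * truth.loc[m, "q"]
            + truth.loc[f, "a_f"]
            + truth.loc[m, "a_m"]
            + pe_f[f]
            + pe_m[m]
            + pair_eff[key]
            + yr_eff[row["year"]]
            + rng.normal(0.0, np.sqrt(cfg.var_residual))
        )
        p = 1.0 / (1.0 + np.exp(-eta))
        n_epo[b] = rng.binomial(int(row["n_offspring"]), p)
    out["n_epo"] = n_epo
    return out
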