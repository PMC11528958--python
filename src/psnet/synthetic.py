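"""Synthetic visit-registry and planted-ERGM-network generators.

The registry generator emulates the *structure* of a one-year primary-care
extract: patients carry a diagnosis-group label (substance / psychosis /
depressive / other) realized as ICD-10 or ICPC-2 codes on a subset of
their visits, professionals have an occupation mix and a home
municipality, visits concentrate on a per-patient "care team", and a
configurable fraction of deliberately dirty rows (home-care visits,
undefined service types, excluded occupations, single-visit and
single-professional patients) gives the filtering cascade real work.

Only aggregate marginals are targeted (occupation shares, visit-count
medians, service-type mix); no attempt is made to match any real joint
distribution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from psnet.cohort import VISIT_COLUMNS
from psnet.errors import ConfigurationError, SpecificationError

_GROUPS = ("substance", "psychosis", "depressive", "other")

#: ICD-10 decades used to realize each diagnosis group.
_GROUP_ICD = {
    "substance": [f"F1{i}" for i in range(10)],
    "psychosis": [f"F2{i}" for i in range(10)],
    "depressive": [f"F3{i}" for i in range(10)],
    "other": [f"F4{i}" for i in range(9)],  # anxiety-spectrum codes
}
_GROUP_ICPC = {"other": ["P74", "P76", "P01"]}

_PHYSICIAN_CODES = ("physician", "gp")
_NURSE_CODES = ("registered_nurse", "practical_nurse", "community_health_nurse")
_OTHER_CODES = ("psychologist", "physiotherapist", "social_worker")
_EXCLUDED_CODES = ("secretary", "manager", "pharmacist", "optician")
_CLASS_CODES = {"physician": _PHYSICIAN_CODES, "nurse": _NURSE_CODES, "other": _OTHER_CODES}


@dataclass(frozen=True)
class VisitCountSpec:
    """Negative-binomial visits-per-patient spec, set by median and dispersion."""

    median: float
    dispersion: float = 2.0


def _default_group_proportions() -> dict:
    # roughly a 10/6/26/58% split across diagnosis groups
    return {"substance": 0.10, "psychosis": 0.06, "depressive": 0.26, "other": 0.58}


def _default_occupation_mix() -> dict:
    return {"physician": 0.26, "nurse": 0.62, "other": 0.12}


def _default_visits_per_patient() -> dict:
    return {
        "substance": VisitCountSpec(20.0),
        "psychosis": VisitCountSpec(21.0),
        "depressive": VisitCountSpec(17.0),
        "other": VisitCountSpec(12.0),
    }


def _default_service_type_mix() -> dict:
    return {"general_care": 0.43, "mh_substance": 0.30, "routine": 0.17, "other": 0.10}


def _default_assortativity() -> dict:
    return {g: 0.3 for g in _GROUPS}


@dataclass
class SyntheticConfig:
    """All generator knobs.  Proportion vectors must sum to 1 (1e-9)."""

    n_patients_total: int = 2000
    group_proportions: dict = field(default_factory=_default_group_proportions)
    n_professionals: int = 300
    occupation_mix: dict = field(default_factory=_default_occupation_mix)
    n_municipalities: int = 7
    visits_per_patient: dict = field(default_factory=_default_visits_per_patient)
    p_within_municipality: float = 0.85
    occupational_assortativity: dict = field(default_factory=_default_assortativity)
    service_type_mix: dict = field(default_factory=_default_service_type_mix)
    diagnosis_visit_fraction: float = 0.3
    team_size_scale: float = 1.0
    team_size_exponent: float = 0.6
    frac_single_visit_patients: float = 0.02
    frac_single_professional_patients: float = 0.02
    frac_home_care_visits: float = 0.01
    frac_undefined_visits: float = 0.01
    frac_excluded_occupation_visits: float = 0.01
    year: int = 2021
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_patients_total", "n_professionals", "n_municipalities"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0 or (
                name != "n_patients_total" and v == 0
            ):
                raise ConfigurationError(f"{name} must be a positive count, got {v!r}")
        for name, vec, keys in (
            ("group_proportions", self.group_proportions, _GROUPS),
            ("occupation_mix", self.occupation_mix, tuple(_CLASS_CODES)),
            ("service_type_mix", self.service_type_mix, None),
        ):
            if keys is not None and set(vec) != set(keys):
                raise ConfigurationError(f"{name} must have keys {keys}, got {set(vec)}")
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 within 1e-9")
            if any(p < 0 for p in vec.values()):
                raise ConfigurationError(f"{name} has a negative entry")
        for g, spec in self.visits_per_patient.items():
            if spec.median < 2:
                raise ConfigurationError(
                    f"visits_per_patient[{g!r}].median must be >= 2, got {spec.median}"
                )
            if spec.dispersion <= 0:
                raise ConfigurationError(
                    f"visits_per_patient[{g!r}].dispersion must be > 0"
                )
        for name in (
            "p_within_municipality",
            "diagnosis_visit_fraction",
            "frac_single_visit_patients",
            "frac_single_professional_patients",
            "frac_home_care_visits",
            "frac_undefined_visits",
            "frac_excluded_occupation_visits",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["visits_per_patient"] = {
            g: {"median": s.median, "dispersion": s.dispersion} if isinstance(s, VisitCountSpec) else s
            for g, s in self.visits_per_patient.items()
        }
        return d

    def write_provenance(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _nbinom_mu_for_median(median: float, dispersion: float) -> float:
    """Mean mu such that NB(r=dispersion, p=r/(r+mu)) has the target median."""
    r = dispersion

    def med(mu: float) -> float:
        return float(stats.nbinom.median(r, r / (r + mu)))

    lo, hi = 0.5, 4.0 * median + 10.0
    while med(hi) < median:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if med(mid) < median:
            lo = mid
        else:
            hi = mid
    return hi


def generate_registry(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a one-year visit table; deterministic for a fixed config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.n_patients_total == 0:
        return pd.DataFrame(columns=list(VISIT_COLUMNS))

    municipalities = [f"M{i + 1}" for i in range(config.n_municipalities)]

    # --- professionals -----------------------------------------------------
    occ_classes = list(_CLASS_CODES)
    occ_p = np.array([config.occupation_mix[c] for c in occ_classes])
    n_pro = config.n_professionals
    pro_class = rng.choice(occ_classes, size=n_pro, p=occ_p)
    pro_code = np.array([rng.choice(_CLASS_CODES[c]) for c in pro_class])
    pro_muni = rng.choice(municipalities, size=n_pro)
    pro_ids = np.array([f"H{i:05d}" for i in range(n_pro)])
    # a few excluded-occupation professionals to exercise the filter
    n_excl = max(1, round(0.02 * n_pro)) if config.frac_excluded_occupation_visits > 0 else 0
    excl_ids = np.array([f"HX{i:04d}" for i in range(n_excl)])
    excl_code = rng.choice(_EXCLUDED_CODES, size=n_excl) if n_excl else np.array([])
    excl_muni = rng.choice(municipalities, size=n_excl) if n_excl else np.array([])

    # index professionals by (municipality, class) for team sampling
    by_cell: dict[tuple[str, str], np.ndarray] = {}
    for m in municipalities:
        for c in occ_classes:
            by_cell[(m, c)] = np.where((pro_muni == m) & (pro_class == c))[0]
    by_class = {c: np.where(pro_class == c)[0] for c in occ_classes}

    # visit share per occupation class, used as the anchor-occupation law
    anchor_p = np.array([0.30, 0.62, 0.08])

    # --- patients ----------------------------------------------------------
    n_pat = config.n_patients_total
    groups = rng.choice(_GROUPS, size=n_pat, p=[config.group_proportions[g] for g in _GROUPS])
    pat_muni = rng.choice(municipalities, size=n_pat)
    pat_ids = np.array([f"P{i:06d}" for i in range(n_pat)])

    mu_cache = {
        g: _nbinom_mu_for_median(s.median, s.dispersion)
        for g, s in config.visits_per_patient.items()
    }
    counts = np.empty(n_pat, dtype=int)
    for g in _GROUPS:
        idx = np.where(groups == g)[0]
        r = config.visits_per_patient[g].dispersion
        mu = mu_cache[g]
        counts[idx] = stats.nbinom.rvs(r, r / (r + mu), size=idx.size, random_state=rng)
    counts = np.maximum(counts, 2)

    single_visit = rng.random(n_pat) < config.frac_single_visit_patients
    counts[single_visit] = 1
    single_pro = (~single_visit) & (rng.random(n_pat) < config.frac_single_professional_patients)

    # qualifying mechanism for the residual "other" group
    mechanism = np.full(n_pat, "icd", dtype=object)
    other_idx = np.where(groups == "other")[0]
    mechanism[other_idx] = rng.choice(
        ["icd", "icpc", "flag"], size=other_idx.size, p=[0.6, 0.2, 0.2]
    )

    service_types = list(config.service_type_mix)
    service_p = np.array([config.service_type_mix[s] for s in service_types])

    rows = []
    for i in range(n_pat):
        g = groups[i]
        n_visits = int(counts[i])
        # --- care team
        if single_pro[i]:
            team_size = 1
        else:
            team_size = max(2, round(config.team_size_scale * n_visits ** config.team_size_exponent))
        anchor = occ_classes[rng.choice(3, p=anchor_p)]
        assort = config.occupational_assortativity[g]
        team: list[int] = []
        guard = 0
        while len(set(team)) < min(team_size, 2 if not single_pro[i] else 1) or len(team) < team_size:
            guard += 1
            if guard > 10 * team_size + 20:
                break
            muni = pat_muni[i] if rng.random() < config.p_within_municipality else rng.choice(municipalities)
            occ = anchor if rng.random() < assort else occ_classes[rng.choice(3, p=anchor_p)]
            cell = by_cell[(muni, occ)]
            if cell.size == 0:
                cell = by_class[occ]
            if cell.size == 0:
                cell = np.arange(n_pro)
            team.append(int(rng.choice(cell)))
        team = sorted(set(team))
        if single_pro[i]:
            team = team[:1]
        weights = rng.dirichlet(np.full(len(team), 0.8))
        assigned = rng.choice(len(team), size=n_visits, p=weights)

        # --- per-visit fields
        dates = np.sort(rng.integers(0, 365, size=n_visits))
        svc = rng.choice(service_types, size=n_visits, p=service_p)
        diag = rng.random(n_visits) < config.diagnosis_visit_fraction
        if mechanism[i] == "flag" and not (svc == "mh_substance").any():
            svc[0] = "mh_substance"
        if mechanism[i] != "flag" and not diag.any():
            diag[0] = True
        home = rng.random(n_visits) < config.frac_home_care_visits
        undef = rng.random(n_visits) < config.frac_undefined_visits
        to_excl = (rng.random(n_visits) < config.frac_excluded_occupation_visits) & (n_excl > 0)

        for k in range(n_visits):
            if to_excl[k]:
                j = int(rng.integers(n_excl))
                hid, code, hmuni = excl_ids[j], excl_code[j], excl_muni[j]
            else:
                j = team[assigned[k]]
                hid, code, hmuni = pro_ids[j], pro_code[j], pro_muni[j]
            service = svc[k]
            if home[k]:
                service = "home_care"
            elif undef[k]:
                service = "undefined"
            icd = ""
            icpc = ""
            if diag[k]:
                if mechanism[i] == "icpc":
                    icpc = str(rng.choice(_GROUP_ICPC["other"]))
                elif mechanism[i] == "icd":
                    icd = str(rng.choice(_GROUP_ICD[g]))
            elif rng.random() < 0.1:
                icd = "Z00"  # unrelated somatic code noise
            day = int(dates[k])
            date = (
                pd.Timestamp(f"{config.year}-01-01") + pd.Timedelta(days=day)
            ).strftime("%Y-%m-%d")
            rows.append(
                (
                    pat_ids[i],
                    hid,
                    date,
                    hmuni,
                    code,
                    service,
                    icd,
                    icpc,
                    service == "mh_substance",
                )
            )

    df = pd.DataFrame(rows, columns=list(VISIT_COLUMNS))
    return df


def generate_ergm_network(
    n_nodes: int,
    occupation_mix: dict,
    n_municipalities: int,
    spec,
    theta,
    seed: int = 0,
):
    """Simulate a network from a dyad-independent ERGM with known truth.

    Node occupations are drawn from ``occupation_mix`` and municipalities
    uniformly; each unordered dyad becomes an edge independently with
    probability logistic(theta . change statistics), via the same code
    path the estimation module uses.
    """
    import networkx as nx

    from psnet import ergm as _ergm

    rng = np.random.default_rng(seed)
    classes = sorted(occupation_mix)
    p = np.array([occupation_mix[c] for c in classes])
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError("occupation_mix must sum to 1 within 1e-9")
    occ = rng.choice(classes, size=n_nodes, p=p)
    muni = rng.choice([f"M{i + 1}" for i in range(n_municipalities)], size=n_nodes)
    g = nx.Graph(min_shared=1)
    for i in range(n_nodes):
        g.add_node(f"N{i:04d}", occupation=str(occ[i]), municipality=str(muni[i]))
    probs, (iu, ju), nodes = _ergm.dyad_probabilities(g, spec, theta)
    draws = rng.random(probs.size) < probs
    g.add_edges_from((nodes[i], nodes[j]) for i, j in zip(iu[draws], ju[draws]))
    return g
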