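"""Shared test construction helpers (no fixtures)."""

import pandas as pd

from psnet.cohort import VISIT_COLUMNS


def visit(patient, professional, date="2021-03-01", muni="M1",
          occ="gp", service="general_care", icd="", icpc="", flag=False):
    return (patient, professional, date, muni, occ, service, icd, icpc, flag)


def make_visits(rows):
    """Build a visit table from 9-tuples (see :func:`visit`)."""
    return pd.DataFrame([tuple(r) for r in rows], columns=list(VISIT_COLUMNS))


def random_bipartite_visits(rng, n_professionals=20, n_patients=100, density=0.2):
    """Random two-mode incidence rendered as a visit table."""
    rows = []
    for p in range(n_patients):
        for h in range(n_professionals):
            if rng.random() < density:
                rows.append(visit(f"p{p:03d}", f"h{h:03d}"))
    return make_visits(rows)
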