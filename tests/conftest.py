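import numpy as np
import pandas as pd
import pytest

import tfcia as t


@pytest.fixture(scope="session")
def reference_sim():
    """One full synthetic dataset at the reference settings (seed 1)."""
    cfg = t.SimulationConfig(seed=1)
    tables, expr, clinical, truth = t.simulate_all(cfg)
    return cfg, tables, expr, clinical, truth


@pytest.fixture()
def small_expr():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(8, 0.5, size=(30, 6)).clip(0),
        index=[f"g{i:03d}" for i in range(30)],
        columns=[f"s{i}" for i in range(6)],
    )
    group_of = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    return t.ExpressionMatrix(values, group_of)


def make_clinical_sites(spec_rows):
    """Build a ClinicalTable from (patient, site_type, score, usable, treated) rows."""
    rows = []
    for i, (pid, stype, score, usable, treated) in enumerate(spec_rows):
        rows.append(
            {
                "patient_id": pid,
                "site_id": f"{pid}_s{i}",
                "site_type": stype,
                "ihc_score": score if usable else np.nan,
                "usable": usable,
                "docetaxel_treated": treated,
                "time_from_diagnosis": 5.0,
                "event_from_diagnosis": True,
                "time_from_crpc": 3.0,
                "event_from_crpc": True,
                "time_from_bone_met": 2.0,
                "event_from_bone_met": True,
            }
        )
    return t.ClinicalTable(pd.DataFrame(rows))
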