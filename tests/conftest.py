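import numpy as np
import pandas as pd
import pytest

from rmctrial.recist import LESION_COLUMNS


def make_timeline(patient_id: str, slds: dict, new_lesions: dict | None = None,
                  n_targets: int = 1) -> pd.DataFrame:
    """Build a lesion table from {week: sld}, splitting SLD over targets.

    ``new_lesions`` maps week -> list of organs growing a new (non-target)
    lesion that week.
    """
    rows = []
    for week, sld in slds.items():
        for j in range(n_targets):
            rows.append(
                dict(
                    patient_id=patient_id,
                    week=week,
                    lesion_id=f"{patient_id}-T{j + 1}",
                    organ="kidney",
                    longest_diameter_mm=sld / n_targets,
                    is_target=True,
                    is_new=False,
                )
            )
    for week, organs in (new_lesions or {}).items():
        for k, organ in enumerate(organs):
            rows.append(
                dict(
                    patient_id=patient_id,
                    week=week,
                    lesion_id=f"{patient_id}-N{k + 1}",
                    organ=organ,
                    longest_diameter_mm=12.0,
                    is_target=False,
                    is_new=True,
                )
            )
    return pd.DataFrame(rows, columns=LESION_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
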