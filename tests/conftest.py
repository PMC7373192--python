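import numpy as np
import pandas as pd
import pytest

from replinoise import CountTable, ReplicateDesign


@pytest.fixture
def tiny_table() -> CountTable:
    """2 kits x 2 replicates, 3 OTUs; kit A and kit B have distinct profiles."""
    counts = np.array(
        [
            [90, 10, 0],
            [85, 15, 0],
            [0, 10, 90],
            [0, 20, 80],
        ]
    )
    return CountTable(["A_r1", "A_r2", "B_r1", "B_r2"], ["Otu001", "Otu002", "Otu003"], counts)


@pytest.fixture
def tiny_design() -> ReplicateDesign:
    rows = []
    for kit in ("A", "B"):
        for r in (1, 2):
            rows.append(
                {
                    "sample_id": f"{kit}_r{r}",
                    "specimen_id": kit,
                    "replicate_index": r,
                    "kit_id": kit,
                    "is_control": False,
                    "sample_type": "dilution",
                    "dilution_label": "neat",
                }
            )
    return ReplicateDesign(pd.DataFrame(rows))


def make_design(
    n_groups: int = 2,
    n_reps: int = 2,
    prefix: str = "G",
    sample_type: str = "dilution",
    dilution: str = "neat",
    control_groups: tuple[str, ...] = (),
) -> ReplicateDesign:
    rows = []
    for g in range(n_groups):
        gid = f"{prefix}{g + 1}"
        for r in range(1, n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{gid}_r{r}",
                    "specimen_id": gid,
                    "replicate_index": r,
                    "kit_id": gid,
                    "is_control": gid in control_groups,
                    "sample_type": sample_type,
                    "dilution_label": dilution,
                }
            )
    return ReplicateDesign(pd.DataFrame(rows))


def random_table(rng: np.random.Generator, design: ReplicateDesign, n_otus: int = 8,
                 depth: int = 500) -> CountTable:
    base = rng.dirichlet(np.ones(n_otus))
    counts = rng.multinomial(depth, base, size=len(design))
    return CountTable(design.sample_ids, [f"Otu{i:03d}" for i in range(n_otus)], counts)
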