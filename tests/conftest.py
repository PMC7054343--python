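import numpy as np
import pandas as pd
import pytest

from stagecna import AberrationCallMatrix, ProbeMap


def make_probe_map(n: int, chrom: str = "chr1", spacing: int = 1000) -> ProbeMap:
    return ProbeMap(pd.DataFrame({
        "probe_id": [f"{chrom}_P{i + 1}" for i in range(n)],
        "chrom": chrom,
        "pos": [(i + 1) * spacing for i in range(n)],
    }))


def concat_probe_maps(*maps: ProbeMap) -> ProbeMap:
    return ProbeMap(pd.concat([m.frame for m in maps], ignore_index=True))


@pytest.fixture
def fig1_matrix() -> AberrationCallMatrix:
    """The illustrative 3-sample x 7-probe chromosome: gains shared by
    S1,S2 over P4-P6 and by S2,S3 over P5-P7."""
    vals = np.array([
        [0, 0, 0, 1, 1, 1, 0],
        [0, 0, 0, 1, 1, 1, 1],
        [0, 0, 0, 0, 1, 1, 1],
    ], dtype=np.int8)
    return AberrationCallMatrix(vals, ["S1", "S2", "S3"], make_probe_map(7), "demo")
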