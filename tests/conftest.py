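import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def g530_panel_fixture():
    from epimap.datasets import g530_panel

    return g530_panel()


@pytest.fixture
def toy_proteome():
    from epimap.records import ProteinRecord

    return [
        ProteinRecord("P1", "P1 first", "AANNINNIA"),
        ProteinRecord("P2", "P2 second", "QQNNI"),
        ProteinRecord("P3", "P3 third", "MAAAAAAAAAANNIKK"),
        ProteinRecord("P4", "P4 motif-free", "MKMPLTGW"),
    ]


def naive_scan(sequence: str, pattern: str) -> list:
    """Exhaustive-window motif scan oracle; 'x'/'.' are wildcards."""
    canonical = set("ACDEFGHIKLMNPQRSTVWY")
    k = len(pattern)
    hits = []
    for start in range(len(sequence) - k + 1):
        window = sequence[start : start + k]
        ok = True
        for p, ch in zip(pattern, window):
            if p in ("x", "."):
                if ch not in canonical:
                    ok = False
                    break
            elif ch != p:
                ok = False
                break
        if ok:
            hits.append(start)
    return hits


@pytest.fixture
def naive_scan_oracle():
    return naive_scan
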