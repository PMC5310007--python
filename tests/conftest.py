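import pandas as pd
import pytest

from caprilnc.expression import ExpressionData
from caprilnc.simulate import SynthConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study at seed 1 (NB dispersion 0.1)."""
    return generate_study(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def quiet_study():
    """Same study conditions at vanishing dispersion, for the recall checks
    that are defined in the near-noiseless limit."""
    return generate_study(SynthConfig(seed=1, nb_dispersion=1e-8))


@pytest.fixture(scope="session")
def big_lnc_study():
    """A study with >= 1000 lncRNA loci for mean-recovery and proportion checks."""
    cfg = SynthConfig(seed=3, n_coding_genes=120, n_lnc_loci=1000,
                      gap_range=(60_000, 100_000), planted_trans_pairs=10,
                      n_group_specific=3)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_pipeline_config():
    """A reduced study for end-to-end pipeline runs."""
    return {
        "seed": 11,
        "synth": {
            "n_coding_genes": 60,
            "n_lnc_loci": 40,
            "planted_trans_pairs": 5,
            "n_group_specific": 2,
        },
    }


def toy_expression(counts: dict[str, list[int]], lengths: dict[str, int],
                   n_per_group: int = 3) -> ExpressionData:
    """Small two-group ExpressionData from plain dicts (3+3 by default)."""
    samples = [f"c{i}" for i in range(n_per_group)] + \
              [f"t{i}" for i in range(n_per_group)]
    design = {s: ("control" if s.startswith("c") else "case") for s in samples}
    df = pd.DataFrame(counts, index=samples).T
    df.columns = samples
    return ExpressionData(counts=df, lengths=pd.Series(lengths), design=design)
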