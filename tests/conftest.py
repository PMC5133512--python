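import numpy as np
import pytest

from famgxe import FamilyTemplate, SimConfig, SnpSpec, CausalSnp


@pytest.fixture
def small_template():
    # 3 generations, 2 children each marrying in, 2 grandchildren per couple:
    # 2 + 2 + 2 + 4 = 10 per family
    return FamilyTemplate(generations=3, sibships=(2, 2))


@pytest.fixture
def small_config(small_template):
    return SimConfig(
        n_families=4,
        family_template=small_template,
        null_snps=[
            SnpSpec(f"chr1:{1000 + j}", "1", 1000 + j, maf)
            for j, maf in enumerate((0.1, 0.2, 0.3, 0.4, 0.5))
        ],
        causal_snps=[],
        n_replicates=2,
        seed=7,
        attach_pcs=False,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(99)
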