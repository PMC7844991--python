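import numpy as np
import pytest

import siglmf.synthetic as syn
from siglmf.config import PipelineConfig


@pytest.fixture(scope="session")
def sig_truth3() -> syn.SignatureTruth:
    return syn.random_signature_truth(3, seed=0)


@pytest.fixture(scope="session")
def planted_mutations(sig_truth3):
    """Planted mutation table at the signature-recovery scale: ~500 close
    runs and >= 5000 isolated draws."""
    maf, paths = syn.gen_mutation_dataset(sig_truth3, n_samples=135,
                                          mean_run_len=4.0, close_frac=0.5,
                                          seed=0, mean_mutations=80.0)
    return maf, paths


@pytest.fixture(scope="session")
def small_panel() -> syn.SyntheticPanel:
    """A compact omics+response panel with a planted factor model and
    mutation data, shared by pipeline-level tests."""
    truth = syn.random_response_truth(40, 8, 3, noise_sd=0.3, seed=7,
                                      factor_scale=1.0)
    panel = syn.gen_omics_response_dataset(40, 8, truth, n_genes=40,
                                           n_signal_genes=12, tissues=3,
                                           missing_frac=0.1, seed=7,
                                           n_cnv_features=24, n_cnv_signal=8)
    return syn.attach_mutation_data(panel, syn.random_signature_truth(2, seed=7),
                                    mean_mutations=40.0, seed=7)


@pytest.fixture()
def light_config() -> PipelineConfig:
    """Pipeline settings scaled for small fixtures (fewer EM iterations,
    lighter forests, pooled Boruta)."""
    return PipelineConfig(seed=0, hidden_units=8, ae_epochs=150,
                          keep_fraction=0.5,
                          boruta_mode="pooled", boruta_max_iter=10,
                          boruta_trees=50, hmm_restarts=1, hmm_max_iter=40,
                          n_signatures=2, n_folds=4, n_repeats=1, L=5)
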