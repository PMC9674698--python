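import numpy as np
import pytest

from mcrepeat.models import ModelSpec, TrainConfig, build_model, train
from mcrepeat.pipeline import head_for_kind, labels_for_head
from mcrepeat.synthetic import GeneratorConfig, JitterSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, fast dataset for training smoke tests (16x16, 36 patients)."""
    cfg = GeneratorConfig(n_patients=36, k=3, image_size=16, seed=123,
                          jitter=JitterSpec(rotation_deg=5.0, translate_px=1))
    return generate_dataset(cfg)


def train_tiny(ds, kind="multiclass", dropout_rate=0.1, epochs=3, seed=0):
    head = head_for_kind(kind, ds.config.k)
    x_tr, y_tr, _ = ds.split("train")
    x_va, y_va, _ = ds.split("val")
    spec = ModelSpec(head=head, dropout_rate=dropout_rate,
                     input_size=ds.config.image_size, seed=seed)
    model = build_model(spec)
    cfg = TrainConfig(epochs=epochs, seed=seed, batch_size=16)
    hist = train(model, x_tr.astype(np.float32), labels_for_head(y_tr, head),
                 x_va.astype(np.float32), labels_for_head(y_va, head), cfg)
    return model, hist


@pytest.fixture(scope="session")
def tiny_mc_model(tiny_dataset):
    model, _ = train_tiny(tiny_dataset, dropout_rate=0.1)
    return model
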