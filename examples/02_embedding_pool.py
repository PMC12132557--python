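"""Train per-modality embedders and assemble the joint embedding pool.

RNA/mutation/image data are encoded by independently trained VAEs (the
image path trains a double-width latent whose output is truncated to its
latter half); annotations use a fixed deterministic semantic map.  The
only coordination is the shared output dimensionality.
"""

from dataclasses import replace

from modagg import CohortConfig, VaeConfig, build_pool, generate_cohort
from modagg.cohort import MODALITIES

D = 192  # shared embedding dimensionality (8x8x3 tiles at this desk scale)

cohort = generate_cohort(
    CohortConfig(
        n_patients_per_type=15,
        embed_dim=D,
        image_multiplicity=("poisson_plus_one", 8.0),
        annotation_multiplicity=("poisson_plus_one", 3.0),
        seed=1,
    )
)

vae = VaeConfig(latent_dim=D, hidden_sizes=(256,), max_epochs=20, patience=8, batch_size=64)
pool = build_pool(
    cohort,
    rna_config=replace(vae, seed=11),
    mutation_config=replace(vae, seed=12),
    image_config=replace(vae, latent_dim=2 * D, seed=13),
    seed=5,
)

print(f"pool: {pool.vectors.shape[0]} embeddings of dimension {pool.embed_dim}")
for m in MODALITIES:
    n = int((pool.modality == m).sum())
    print(f"  {m:10s} {n:5d} embeddings")
# RNA and mutation contribute exactly one embedding per patient; image and
# annotation counts follow the configured per-patient multiplicities.
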