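"""Filter peptide-spectrum matches and estimate the decoy FDR.

Acceptance rules: E-value <= 0.01; one best match per (tissue, spectrum)
across all database partitions and search spaces; single-spectrum
identifications rejected unless two engines agree.  Decoy matches travel
the identical path, and FDR% = 100 x decoys / targets.

Here the E-value law is identical for targets and decoys (a pure-noise
null), so the estimated FDR should be ~100%: the estimator is calibrated.
"""

from pgmap.fixtures import simulate_null_psms
from pgmap.models import PSM
from pgmap.psm import compute_fdr, filter_pipeline

df = simulate_null_psms(n_pairs=2500, seed=2)  # 10 000 PSM rows
psms = [PSM(r.spectrum_id, r.peptide, float(r.evalue), r.engine,
            r.search_space, r.partition, bool(r.is_decoy), r.tissue)
        for r in df.itertuples()]

hits = filter_pipeline(psms)
n_target = sum(1 for h in hits if not h.is_decoy)
n_decoy = sum(1 for h in hits if h.is_decoy)

print(f"simulated PSMs: {len(psms)} (half decoys, same E-value law)")
print(f"surviving peptide hits: {n_target} target / {n_decoy} decoy")
print(f"estimated FDR: {compute_fdr(n_target, n_decoy)}%  (expect ~100%)")
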