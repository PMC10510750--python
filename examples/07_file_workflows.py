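"""File-driven workflow: model/tracer/measurements on disk -> fit artifacts.

Mirrors how the library is scripted in a pipeline: all inputs are plain
text (TSV/YAML), all outputs are written next to a run.log that records the
seed, so every artifact is regenerable.
"""

import tempfile
from pathlib import Path

from emuflux import io as efio
from emuflux.fixtures import generate_synthetic_dataset, toynet1
from emuflux.workflows import RunConfig, report, run_fit

spec = toynet1()
work = Path(tempfile.mkdtemp(prefix="emuflux_"))

(work / "model.tsv").write_text(spec.reactions_tsv)
efio.write_tracer_yaml(spec.strategy, work / "tracer.yaml")
ds = generate_synthetic_dataset(spec, noise_molpct=1.0, seed=13)
efio.write_mdv_measurements(ds.mdv_measurements, work / "mdv.tsv")
efio.write_flux_measurements(ds.flux_measurements, work / "flux.tsv")

cfg = RunConfig(model=str(work / "model.tsv"),
                tracer=str(work / "tracer.yaml"),
                mdv_measurements=str(work / "mdv.tsv"),
                flux_measurements=str(work / "flux.tsv"),
                out_dir=str(work / "fit"), n_starts=3, seed=5)
fit = run_fit(cfg)
print("artifacts:", sorted(p.name for p in (work / "fit").iterdir()))

rep = report(work / "fit")
print(f"Phi = {rep['phi']:.2f} (dof {rep['dof']}), chi2 "
      f"{'accepted' if rep['chi2_accepted'] else 'rejected'}, "
      f"max |weighted residual| = {rep['max_abs_z']:.2f}")
print("fitted net fluxes:", {r['reaction_id']: round(r['net'], 2)
                             for r in rep['fluxes']})
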