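"""Stage implementations behind :func:`protomerscope.pipeline.run_pipeline`.

Each stage is a pure function of (config, inputs): it reads its input files,
runs the corresponding library operations, writes TSV tables / JSON reports
into ``config.outputs`` and returns the list of files written.  No stage
mutates its inputs.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .classify import classify_structure
from .ensemble import compute_timeseries, distribution, state_probability
from .fingerprint import build_fingerprint
from .metrics import metric_record
from .network import (
    contact_probabilities,
    difference_network,
    partition_communities,
    stable_contacts,
)
from .structure import read_structure, read_trajectory
from .synthetic import ScaffoldSpec, TrajectorySchedule, make_dimer, make_trajectory


def _out(config, name):
    return os.path.join(config.outputs, name)


def stage_metrics(config, inputs):
    structure = read_structure(inputs["structure"])
    protomer = inputs.get("protomer")
    labels = [protomer] if protomer else list(structure.protomer_labels())
    ligand = inputs.get("ligand")
    rows = []
    for label in labels:
        lig = structure.ligand_for_protomer(label, name=ligand) if ligand else None
        rows.append(
            metric_record(
                structure, label, config.anchors, config.thresholds, ligand=lig
            ).as_dict()
        )
    path = _out(config, "metrics.tsv")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return [path]


def stage_fingerprint(config, inputs):
    structure = read_structure(inputs["structure"])
    protomer = inputs.get("protomer") or structure.protomer_labels()[0]
    lig = structure.ligand_for_protomer(protomer, name=inputs["ligand"])
    if lig is None:
        raise ValueError(f"no ligand {inputs['ligand']!r} in protomer {protomer!r}")
    fp = build_fingerprint(structure, protomer, lig, thresholds=config.thresholds)
    tsv = _out(config, "fingerprint.tsv")
    fp.as_table().to_csv(tsv, sep="\t", index=False)
    js = _out(config, "fingerprint.json")
    with open(js, "w") as fh:
        json.dump(
            {
                "ligand": fp.ligand_id,
                "protomer": fp.protomer,
                "records": [r.__dict__ for r in fp.records],
            },
            fh,
            indent=2,
        )
    return [tsv, js]


def stage_classify(config, inputs):
    structure = read_structure(inputs["structure"])
    call = classify_structure(
        structure, inputs["ligand"], config.anchors, config.thresholds
    )
    path = _out(config, "selectivity.json")
    with open(path, "w") as fh:
        json.dump(call.as_dict(), fh, indent=2)
    return [path]


def stage_ensemble(config, inputs):
    ens = read_trajectory(
        inputs["topology"], inputs["frames"], config.burn_in_fraction
    )
    metric = inputs.get("metric", "alpha_c")
    series = compute_timeseries(
        ens, metric, config.anchors, config.thresholds, ligand=inputs.get("ligand")
    )
    written = []
    rows = []
    for r, vals in enumerate(series.values):
        for f in range(vals.shape[0]):
            for p, label in enumerate(series.protomer_labels):
                rows.append(
                    {"replica": r, "frame": f, "protomer": label,
                     "value": vals[f, p]}
                )
    ts = _out(config, f"timeseries_{metric}.tsv")
    pd.DataFrame(rows).to_csv(ts, sep="\t", index=False)
    written.append(ts)

    pool = not inputs.get("per_protomer", False)
    dist = distribution(series, n_bins=config.n_bins, pool_protomers=pool)
    dists = dist if isinstance(dist, dict) else {"pooled": dist}
    for name, d in dists.items():
        hp = _out(config, f"histogram_{metric}_{name}.tsv")
        pd.DataFrame(
            {
                "bin_left": d.bin_edges[:-1],
                "bin_right": d.bin_edges[1:],
                "probability": d.probabilities,
            }
        ).to_csv(hp, sep="\t", index=False)
        written.append(hp)

    predicate = {"alpha_c": "alpha_c_in", "ke": "salt_bridge",
                 "dfg": "dfg_in", "lig501": "glu501_hbond"}[metric]
    est = state_probability(series, predicate, config.thresholds)
    pj = _out(config, f"probability_{metric}.json")
    with open(pj, "w") as fh:
        json.dump(
            {"predicate": predicate, "per_replica": list(est.per_replica),
             "mean": est.mean, "sd": est.sd},
            fh,
            indent=2,
        )
    written.append(pj)
    return written


def stage_dcna(config, inputs):
    k = int(inputs.get("k", 4))
    apo_ens = read_trajectory(inputs["topology"], inputs["apo"], config.burn_in_fraction)
    holo_ens = read_trajectory(inputs["topology"], inputs["holo"], config.burn_in_fraction)
    apo = contact_probabilities(apo_ens, config.thresholds)
    holo = contact_probabilities(holo_ens, config.thresholds)
    written = []
    for name, mat in (("apo", apo), ("holo", holo)):
        path = _out(config, f"contacts_{name}.tsv")
        labels = [f"{p}:{r}" for p, r in mat.residue_index]
        pd.DataFrame(mat.probabilities, index=labels, columns=labels).to_csv(
            path, sep="\t"
        )
        written.append(path)
    graph = stable_contacts(holo, config.thresholds)
    # partition on the union graph so both states share one community map
    union = stable_contacts(apo, config.thresholds)
    for u, v, d in graph.edges(data=True):
        if not union.has_edge(u, v) or union[u][v]["weight"] < d["weight"]:
            union.add_edge(u, v, weight=d["weight"])
    partition = partition_communities(union, k=k)
    pj = _out(config, "communities.json")
    with open(pj, "w") as fh:
        json.dump(
            {f"{p}:{r}": c for (p, r), c in partition.assignment.items()},
            fh,
            indent=2,
        )
    written.append(pj)
    diff = difference_network(apo, holo, partition, config.thresholds)
    dj = _out(config, "difference_network.json")
    with open(dj, "w") as fh:
        json.dump(diff.as_dict(), fh, indent=2)
    written.append(dj)
    return written


def stage_simulate(config, inputs):
    spec_kw = dict(inputs.get("spec", {}))
    fractions = spec_kw.pop("state_fractions", {"salt_bridge_on": 0.6})
    n_frames = int(spec_kw.pop("n_frames", 200))
    n_replicas = int(spec_kw.pop("n_replicas", 3))
    sigma = float(spec_kw.pop("noise_sigma", 0.05))
    base = make_dimer(ScaffoldSpec(**spec_kw), ScaffoldSpec(**spec_kw))
    schedule = TrajectorySchedule(
        n_frames=n_frames,
        n_replicas=n_replicas,
        state_fractions=fractions,
        noise_sigma=sigma,
        seed=config.seed,
    )
    prefix = _out(config, inputs.get("prefix", "synthetic"))
    make_trajectory(base, schedule, out_prefix=prefix)
    return [f"{prefix}_rep{r + 1}.pdb" for r in range(n_replicas)] + [
        f"{prefix}_manifest.json"
    ]
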