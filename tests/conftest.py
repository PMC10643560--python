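import numpy as np
import pytest

from ikgm.io_formats import ProteinRecord, SpeciesGenome, Manifest, ManifestRow


@pytest.fixture
def tiny_genome():
    return SpeciesGenome(
        species_id="sp1",
        label="diurnal",
        proteins=(
            ProteinRecord("p1", "MKVAAAMKV", domains=("PF00001", "PF00002")),
            ProteinRecord("p2", "ACDEFGHIKLMNPQRSTVWY", domains=("PF00002",)),
            ProteinRecord("p3", "MKVMKVMKV", domains=("PF00003",)),
        ),
    )


@pytest.fixture
def two_taxa_genomes(rng=None):
    rng = np.random.default_rng(42)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    genomes = []
    for label, prefix in (("diurnal", "d"), ("nocturnal", "n")):
        for s in range(2):
            proteins = tuple(
                ProteinRecord(
                    f"{prefix}{s}_p{i}",
                    "".join(rng.choice(aa, size=60)),
                    domains=(f"PF{i:05d}",),
                )
                for i in range(8)
            )
            genomes.append(SpeciesGenome(f"{prefix}{s}", label, proteins))
    return genomes


@pytest.fixture
def manifest_two_taxa():
    return Manifest(
        (
            ManifestRow("d0", "diurnal", "d0.fasta"),
            ManifestRow("d1", "diurnal", "d1.fasta"),
            ManifestRow("n0", "nocturnal", "n0.fasta"),
            ManifestRow("n1", "nocturnal", "n1.fasta"),
        )
    )
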