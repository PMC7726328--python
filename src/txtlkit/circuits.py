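"""Circuit descriptions for cell-free TX/TL gene expression models.

A circuit is a set of genes, each carrying a promoter model made of
statistical-mechanical configurations (ground state, RNAP-bound,
activator/repressor-bound), plus constitutive regulator species such as
sigma factor 70 that are present in the extract but not encoded on a
plasmid. Characteristic constants (polymerase/ribosome pools, elongation
rates, saturation constants, default degradation rates) live alongside the
structure so that a :class:`CircuitSpec` plus a :class:`ParameterSet` is a
complete, simulatable model instance.

Two built-in circuits are provided:

* ``C1`` — sigma70-driven expression of the deGFP reporter (one gene,
  11 free parameters).
* ``C2`` — a negative-feedback loop in which sigma70 drives sigma28 and
  deGFP-ssrA, sigma28 drives cI-ssrA, and cI-ssrA represses both P70a
  promoters (three genes, 33 free parameters).

Internal units are nM for concentrations, hours for time, kJ/mol for
configuration Gibbs energies, nt/aa for lengths.
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass, field, asdict

import yaml

__all__ = [
    "GeneDescriptor",
    "RegulatorBinding",
    "PromoterConfiguration",
    "PromoterModel",
    "ConstitutiveSpecies",
    "CharacteristicConstants",
    "CircuitSpec",
    "ParameterSet",
    "CircuitConfigError",
    "load_circuit",
    "serialize_circuit",
    "validate_circuit",
    "builtin_circuit",
    "apply_parameters",
    "free_parameter_names",
]

#: Ideal gas constant, kJ mol^-1 K^-1.
R_GAS = 8.314e-3

#: Minutes and days to hours.
MIN = 1.0 / 60.0
DAY = 24.0

LN2 = math.log(2.0)


class CircuitConfigError(ValueError):
    """Raised when a circuit configuration fails to parse or validate."""


@dataclass
class RegulatorBinding:
    """Hill-type binding of a transcription factor within one configuration.

    ``dissociation_constant`` is in nM; ``sense`` is ``"activator"`` or
    ``"repressor"``. Repressor-bound configurations never express, so their
    bound fraction appears only in the partition-function denominator.
    """

    regulator: str
    dissociation_constant: float
    hill_coefficient: float
    sense: str = "activator"


@dataclass
class PromoterConfiguration:
    """One statistical-mechanical promoter state.

    The ground configuration has ``gibbs_energy == 0`` (weight exactly 1)
    and does not express. ``expressing`` marks membership in the set of
    configurations that lead to transcription.
    """

    label: str
    gibbs_energy: float  # kJ/mol
    binding: RegulatorBinding | None = None
    expressing: bool = False

    @property
    def is_ground(self) -> bool:
        return self.label == "ground"


@dataclass
class PromoterModel:
    """Ordered set of configurations for one gene's promoter."""

    configurations: list[PromoterConfiguration]

    def configuration(self, label: str) -> PromoterConfiguration:
        for c in self.configurations:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass
class GeneDescriptor:
    """A plasmid-borne gene: concentrations, lengths, and kinetic modifiers.

    Degradation modifiers are dimensionless multipliers on the circuit's
    default mRNA/protein degradation rate constants; time constants are the
    dimensionless initiation-to-elongation ratios for transcription and
    translation (small values mean elongation-limited kinetics).
    """

    name: str
    gene_conc: float  # nM
    gene_length: int  # nt
    protein_length: int  # aa
    mrna_deg_modifier: float = 1.0
    protein_deg_modifier: float = 1.0
    tx_time_constant: float | None = None
    tl_time_constant: float | None = None


@dataclass
class ConstitutiveSpecies:
    """A regulator present in the extract with no encoding gene (sigma70)."""

    name: str
    initial_conc: float  # nM
    protein_deg_modifier: float = 1.0


@dataclass
class CharacteristicConstants:
    """Characteristic TX/TL constants of the cell-free reaction.

    Defaults reflect an E. coli extract incubated at 29 C: 75 nM core RNA
    polymerase, a 2 uM ribosome pool, elongation at 30 nt/s and 1.5 aa/s,
    and first-order default degradation of mRNA and protein.
    """

    rnap_total: float = 75.0  # nM
    ribosome_total: float = 2000.0  # nM
    tx_elongation_rate: float = 30.0 * 3600.0  # nt/h
    tl_elongation_rate: float = 1.5 * 3600.0  # aa/h
    tx_saturation: float = 36.0  # nM
    tl_saturation: float = 1.0e5  # nM
    polysome_gain: float = 10.0
    tx_initiation_time: float = 22.0  # s
    tl_initiation_time: float = 1.5  # s
    mrna_deg_default: float = 3.75  # 1/h
    protein_deg_default: float = 0.93  # 1/h, geometric middle of 0.462-1.89
    temperature: float = 302.15  # K
    capacity_halflife: float = 4.0  # h


@dataclass
class CircuitSpec:
    """Complete declarative description of a cell-free genetic circuit."""

    genes: list[GeneDescriptor]
    promoters: dict[str, PromoterModel]
    constitutive_species: list[ConstitutiveSpecies] = field(default_factory=list)
    initial_conditions: dict[str, float] = field(default_factory=dict)
    constants: CharacteristicConstants = field(default_factory=CharacteristicConstants)
    name: str = "circuit"

    # -- species bookkeeping -------------------------------------------------
    def gene(self, name: str) -> GeneDescriptor:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def mrna_species(self) -> list[str]:
        return [f"mRNA_{g.name}" for g in self.genes]

    def protein_species(self) -> list[str]:
        return [g.name for g in self.genes] + [s.name for s in self.constitutive_species]

    def species_names(self) -> list[str]:
        return self.mrna_species() + self.protein_species() + ["capacity"]

    def regulator_pool(self) -> set[str]:
        return {g.name for g in self.genes} | {s.name for s in self.constitutive_species}

    def initial_value(self, species: str) -> float:
        if species in self.initial_conditions:
            return self.initial_conditions[species]
        if species == "capacity":
            return 1.0
        for s in self.constitutive_species:
            if s.name == species:
                return s.initial_conc
        return 0.0


@dataclass
class ParameterSet:
    """Named free-parameter values for one model instance (model units).

    Keys follow the convention ``K_L``, ``tau_L_half``, ``tau_X_<gene>``,
    ``tau_L_<gene>``, ``theta_m_<gene>``, ``theta_p_<species>``,
    ``dG_<gene>_<regulator|RNAP>``, ``n_<gene>_<regulator>``,
    ``K_<gene>_<regulator>``. Degradation rates are absolute (1/h),
    dissociation constants nM, energies kJ/mol.
    """

    values: dict[str, float]
    circuit: str | None = None

    def names(self) -> list[str]:
        return list(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def replace(self, **updates: float) -> "ParameterSet":
        unknown = set(updates) - set(self.values)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        vals = dict(self.values)
        vals.update(updates)
        return ParameterSet(vals, circuit=self.circuit)


# ---------------------------------------------------------------------------
# validation


def validate_circuit(spec: CircuitSpec) -> list[str]:
    """Check every structural invariant; return one diagnostic per violation.

    An empty list means the spec is valid. Diagnostics name the offending
    field so they can be surfaced directly to a config author.
    """
    diags: list[str] = []
    pool = spec.regulator_pool()

    if not spec.genes:
        diags.append("genes: circuit must declare at least one gene")
    seen: set[str] = set()
    for g in spec.genes:
        ctx = f"gene '{g.name}'"
        if g.name in seen:
            diags.append(f"{ctx}: duplicate gene name")
        seen.add(g.name)
        if g.gene_conc < 0:
            diags.append(f"{ctx}: gene_conc must be >= 0 (got {g.gene_conc})")
        if g.gene_length <= 0:
            diags.append(f"{ctx}: gene_length must be > 0 (got {g.gene_length})")
        if g.protein_length <= 0:
            diags.append(f"{ctx}: protein_length must be > 0 (got {g.protein_length})")
        for fname in ("mrna_deg_modifier", "protein_deg_modifier",
                      "tx_time_constant", "tl_time_constant"):
            v = getattr(g, fname)
            if v is None or v <= 0:
                diags.append(f"{ctx}: {fname} must be > 0 (got {v})")
        if g.name not in spec.promoters:
            diags.append(f"{ctx}: no promoter model declared")

    for s in spec.constitutive_species:
        if s.initial_conc < 0:
            diags.append(f"constitutive '{s.name}': initial_conc must be >= 0")
        if s.protein_deg_modifier <= 0:
            diags.append(f"constitutive '{s.name}': protein_deg_modifier must be > 0")

    for gname, model in spec.promoters.items():
        ctx = f"promoter '{gname}'"
        grounds = [c for c in model.configurations if c.is_ground]
        if len(grounds) != 1:
            diags.append(f"{ctx}: must contain exactly one ground configuration "
                         f"(found {len(grounds)})")
        for c in grounds:
            if c.gibbs_energy != 0.0:
                diags.append(f"{ctx}: ground configuration must have gibbs_energy = 0")
            if c.expressing:
                diags.append(f"{ctx}: ground configuration must not be expressing")
        if not any(c.expressing for c in model.configurations):
            diags.append(f"{ctx}: needs at least one expressing configuration")
        for c in model.configurations:
            if c.binding is None:
                continue
            b = c.binding
            bctx = f"{ctx} configuration '{c.label}'"
            if b.regulator not in pool:
                diags.append(f"{bctx}: regulator '{b.regulator}' is neither a gene "
                             f"product nor a constitutive species")
            if b.dissociation_constant <= 0:
                diags.append(f"{bctx}: dissociation_constant must be > 0")
            if b.hill_coefficient <= 0:
                diags.append(f"{bctx}: hill_coefficient must be > 0")
            if b.sense not in ("activator", "repressor"):
                diags.append(f"{bctx}: sense must be 'activator' or 'repressor'")
            if b.sense == "repressor" and c.expressing:
                diags.append(f"{bctx}: repressor-bound configurations cannot express")

    c = spec.constants
    for fname, v in asdict(c).items():
        if v <= 0:
            diags.append(f"constants.{fname}: must be > 0 (got {v})")

    for sp, v in spec.initial_conditions.items():
        if sp != "capacity" and v < 0:
            diags.append(f"initial_conditions['{sp}']: must be >= 0")
        if sp == "capacity" and not (0.0 <= v <= 1.0):
            diags.append("initial_conditions['capacity']: must be within [0, 1]")

    return diags


# ---------------------------------------------------------------------------
# config I/O (YAML dialect)


def _seed_time_constants(g: GeneDescriptor, c: CharacteristicConstants) -> None:
    # Baseline tau = initiation time / elongation time, both in seconds.
    if g.tx_time_constant is None:
        elong_s = g.gene_length / (c.tx_elongation_rate / 3600.0)
        g.tx_time_constant = c.tx_initiation_time / elong_s
    if g.tl_time_constant is None:
        elong_s = g.protein_length / (c.tl_elongation_rate / 3600.0)
        g.tl_time_constant = c.tl_initiation_time / elong_s


def load_circuit(config_text: str) -> CircuitSpec:
    """Parse a YAML circuit config into a validated :class:`CircuitSpec`.

    Top-level keys: ``name``, ``constants``, ``genes``, ``promoters``,
    ``constitutive``, ``initial_conditions``. Concentrations are nM,
    energies kJ/mol, lengths nt/aa, rates per hour. Omitted constants take
    the :class:`CharacteristicConstants` defaults; omitted gene time
    constants are seeded from the initiation and elongation times.
    """
    try:
        raw = yaml.safe_load(io.StringIO(config_text))
    except yaml.YAMLError as exc:
        raise CircuitConfigError(f"config does not parse as YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise CircuitConfigError("config root must be a mapping")

    known = {"name", "constants", "genes", "promoters", "constitutive",
             "initial_conditions"}
    extra = set(raw) - known
    if extra:
        raise CircuitConfigError(f"unknown top-level keys: {sorted(extra)}")

    cdata = raw.get("constants") or {}
    cfields = {f for f in CharacteristicConstants.__dataclass_fields__}
    bad = set(cdata) - cfields
    if bad:
        raise CircuitConfigError(f"constants: unknown keys {sorted(bad)}")
    constants = CharacteristicConstants(**cdata)

    genes: list[GeneDescriptor] = []
    for gd in raw.get("genes") or []:
        try:
            genes.append(GeneDescriptor(**gd))
        except TypeError as exc:
            raise CircuitConfigError(f"genes entry {gd!r}: {exc}") from exc
    for g in genes:
        _seed_time_constants(g, constants)

    promoters: dict[str, PromoterModel] = {}
    for gname, confs in (raw.get("promoters") or {}).items():
        configurations = [PromoterConfiguration("ground", 0.0)]
        for cd in confs:
            cd = dict(cd)
            if cd.get("label") == "ground":
                continue  # implicit ground is always present
            bdata = cd.pop("binding", None)
            binding = RegulatorBinding(**bdata) if bdata else None
            try:
                configurations.append(PromoterConfiguration(binding=binding, **cd))
            except TypeError as exc:
                raise CircuitConfigError(
                    f"promoter '{gname}' configuration {cd!r}: {exc}") from exc
        promoters[gname] = PromoterModel(configurations)

    constitutive = [ConstitutiveSpecies(**sd) for sd in raw.get("constitutive") or []]

    spec = CircuitSpec(
        genes=genes,
        promoters=promoters,
        constitutive_species=constitutive,
        initial_conditions=dict(raw.get("initial_conditions") or {}),
        constants=constants,
        name=raw.get("name", "circuit"),
    )
    diags = validate_circuit(spec)
    if diags:
        raise CircuitConfigError("invalid circuit config:\n  " + "\n  ".join(diags))
    return spec


def serialize_circuit(spec: CircuitSpec) -> str:
    """Emit the YAML config dialect; ``load_circuit`` round-trips it."""
    out: dict = {"name": spec.name, "constants": asdict(spec.constants)}
    out["genes"] = [asdict(g) for g in spec.genes]
    proms: dict = {}
    for gname, model in spec.promoters.items():
        confs = []
        for c in model.configurations:
            if c.is_ground:
                continue
            cd: dict = {"label": c.label, "gibbs_energy": c.gibbs_energy,
                        "expressing": c.expressing}
            if c.binding is not None:
                cd["binding"] = asdict(c.binding)
            confs.append(cd)
        proms[gname] = confs
    out["promoters"] = proms
    out["constitutive"] = [asdict(s) for s in spec.constitutive_species]
    out["initial_conditions"] = dict(spec.initial_conditions)
    return yaml.safe_dump(out, sort_keys=False)


# ---------------------------------------------------------------------------
# free-parameter plumbing


def _resolve_gene_suffix(spec: CircuitSpec, tail: str) -> tuple[str, str]:
    """Split '<gene>_<key>' where gene names may themselves contain '_'."""
    candidates = sorted((g.name for g in spec.genes), key=len, reverse=True)
    for gname in candidates:
        if tail == gname:
            return gname, ""
        if tail.startswith(gname + "_"):
            return gname, tail[len(gname) + 1:]
    raise KeyError(f"no gene of the circuit prefixes '{tail}'")


def _resolve_regulator(spec: CircuitSpec, key: str) -> str:
    pool = spec.regulator_pool()
    if key in pool:
        return key
    hits = sorted(s for s in pool if s.startswith(key))
    if len(hits) == 1:
        return hits[0]
    raise KeyError(f"regulator key '{key}' matches {hits or 'nothing'} in the circuit")


def _find_configuration(spec: CircuitSpec, gene: str, key: str) -> PromoterConfiguration:
    model = spec.promoters[gene]
    if key == "RNAP":
        for c in model.configurations:
            if c.label == "RNAP" and c.binding is None:
                return c
        raise KeyError(f"promoter '{gene}' has no bare-RNAP configuration")
    reg = _resolve_regulator(spec, key)
    for c in model.configurations:
        if c.binding is not None and c.binding.regulator == reg:
            return c
    raise KeyError(f"promoter '{gene}' has no configuration bound by '{reg}'")


def _protein_deg_target(spec: CircuitSpec, key: str):
    reg = _resolve_regulator(spec, key)
    for g in spec.genes:
        if g.name == reg:
            return g
    for s in spec.constitutive_species:
        if s.name == reg:
            return s
    raise KeyError(key)


def apply_parameters(spec: CircuitSpec, params: ParameterSet) -> CircuitSpec:
    """Return a deep copy of ``spec`` with the named free parameters applied.

    Absolute degradation rates are folded into the gene/species modifiers
    relative to the circuit's default rate constants, so the returned spec
    simulates with exactly the rates in ``params``.
    """
    spec = copy.deepcopy(spec)
    c = spec.constants
    for name, value in params.values.items():
        try:
            if name == "K_L":
                c.tl_saturation = value
            elif name == "tau_L_half":
                c.capacity_halflife = value
            elif name.startswith("tau_X_"):
                gene, _ = _resolve_gene_suffix(spec, name[len("tau_X_"):])
                spec.gene(gene).tx_time_constant = value
            elif name.startswith("tau_L_"):
                gene, _ = _resolve_gene_suffix(spec, name[len("tau_L_"):])
                spec.gene(gene).tl_time_constant = value
            elif name.startswith("theta_m_"):
                gene, _ = _resolve_gene_suffix(spec, name[len("theta_m_"):])
                spec.gene(gene).mrna_deg_modifier = value / c.mrna_deg_default
            elif name.startswith("theta_p_"):
                target = _protein_deg_target(spec, name[len("theta_p_"):])
                target.protein_deg_modifier = value / c.protein_deg_default
            elif name.startswith("dG_"):
                gene, key = _resolve_gene_suffix(spec, name[len("dG_"):])
                _find_configuration(spec, gene, key).gibbs_energy = value
            elif name.startswith("n_"):
                gene, key = _resolve_gene_suffix(spec, name[len("n_"):])
                _find_configuration(spec, gene, key).binding.hill_coefficient = value
            elif name.startswith("K_"):
                gene, key = _resolve_gene_suffix(spec, name[len("K_"):])
                _find_configuration(spec, gene, key).binding.dissociation_constant = value
            else:
                raise KeyError("unrecognized parameter name")
        except KeyError as exc:
            raise KeyError(f"cannot apply parameter '{name}': {exc}") from exc
    return spec


def free_parameter_names(spec: CircuitSpec) -> list[str]:
    """Canonical free-parameter enumeration for an arbitrary circuit.

    Order: global translation saturation and capacity half-life; per-gene
    time constants and degradation rates; constitutive protein stabilities;
    per-configuration Gibbs energies; Hill coefficients and dissociation
    constants of every binding.
    """
    def key(reg: str) -> str:
        # degradation-tagged regulators go by their bare protein name
        return reg[:-5] if reg.endswith("_ssrA") else reg

    names = ["K_L", "tau_L_half"]
    for g in spec.genes:
        names += [f"tau_X_{g.name}", f"tau_L_{g.name}",
                  f"theta_m_{g.name}", f"theta_p_{g.name}"]
    for s in spec.constitutive_species:
        names.append(f"theta_p_{s.name}")
    for g in spec.genes:
        for conf in spec.promoters[g.name].configurations:
            if conf.is_ground:
                continue
            suffix = "RNAP" if conf.binding is None else key(conf.binding.regulator)
            names.append(f"dG_{g.name}_{suffix}")
    for g in spec.genes:
        for conf in spec.promoters[g.name].configurations:
            if conf.binding is not None:
                names.append(f"n_{g.name}_{key(conf.binding.regulator)}")
    for g in spec.genes:
        for conf in spec.promoters[g.name].configurations:
            if conf.binding is not None:
                names.append(f"K_{g.name}_{key(conf.binding.regulator)}")
    return names


# ---------------------------------------------------------------------------
# built-in circuits

# Estimated means for the sigma70 -> deGFP circuit. Half-lives are converted
# to first-order rate constants in 1/h; dissociation constants uM -> nM.
_C1_PARAMS = {
    "K_L": 483.13e3,                      # nM (483.13 uM)
    "tau_L_half": 4.03,                   # h
    "tau_X_deGFP": 0.61,
    "tau_L_deGFP": 0.16,
    "theta_m_deGFP": LN2 / (13.5 * MIN),  # 13.5 min mRNA half-life
    "theta_p_deGFP": LN2 / (10.86 * DAY),
    "theta_p_sigma70": LN2 / (3.65 * DAY),
    "dG_deGFP_RNAP": 28.82,
    "dG_deGFP_sigma70": -20.38,
    "n_deGFP_sigma70": 1.12,
    "K_deGFP_sigma70": 24.19e3,           # nM (24.19 uM)
}

# Estimated means for the negative-feedback circuit. The sigma28-activated
# configuration of the cI-ssrA promoter carries an energy printed in J/mol
# (-1.10 J/mol), three orders below the other entries; it is kept as printed
# and converted to kJ/mol here.
_C2_PARAMS = {
    "K_L": 253.75e3,
    "tau_L_half": 8.86,
    "tau_X_cI_ssrA": 0.001,               # printed as an upper bound <0.001
    "tau_X_deGFP_ssrA": 0.045,
    "tau_X_sigma28": 0.0018,
    "tau_L_cI_ssrA": 0.054,
    "tau_L_deGFP_ssrA": 0.058,
    "tau_L_sigma28": 1.1,
    "theta_m_cI_ssrA": LN2 / (8.1 * MIN),
    "theta_m_deGFP_ssrA": LN2 / (7.74 * MIN),
    "theta_m_sigma28": LN2 / (14.96 * MIN),
    "theta_p_cI_ssrA": LN2 / (0.46 * DAY),
    "theta_p_deGFP_ssrA": LN2 / (0.051 * DAY),
    "theta_p_sigma28": LN2 / (7.65 * DAY),
    "theta_p_sigma70": LN2 / (14.86 * DAY),
    "dG_cI_ssrA_RNAP": 46.57,
    "dG_cI_ssrA_sigma28": -1.10e-3,       # kJ/mol (printed -1.10 J/mol)
    "dG_deGFP_ssrA_RNAP": 41.94,
    "dG_deGFP_ssrA_sigma70": -27.67,
    "dG_deGFP_ssrA_cI": -7.21,
    "dG_sigma28_RNAP": 46.67,
    "dG_sigma28_sigma70": -10.46,
    "dG_sigma28_cI": -12.89,
    "n_cI_ssrA_sigma28": 1.88,
    "n_deGFP_ssrA_sigma70": 1.53,
    "n_deGFP_ssrA_cI": 0.698,
    "n_sigma28_sigma70": 1.10,
    "n_sigma28_cI": 1.51,
    "K_cI_ssrA_sigma28": 1.09e3,
    "K_deGFP_ssrA_sigma70": 86.87e3,
    "K_deGFP_ssrA_cI": 3.83e3,
    "K_sigma28_sigma70": 1.35e3,
    "K_sigma28_cI": 0.0389e3,
}


def _p70a(dg_rnap: float, dg_sigma70: float, K70: float, n70: float,
          repressor: tuple[float, float, float] | None = None) -> PromoterModel:
    """P70a promoter: ground, bare RNAP, sigma70-activated, optional cI-bound."""
    confs = [
        PromoterConfiguration("ground", 0.0),
        PromoterConfiguration("RNAP", dg_rnap, expressing=True),
        PromoterConfiguration(
            "RNAP_sigma70", dg_sigma70,
            binding=RegulatorBinding("sigma70", K70, n70, "activator"),
            expressing=True),
    ]
    if repressor is not None:
        dg, K, n = repressor
        confs.append(PromoterConfiguration(
            "cI", dg,
            binding=RegulatorBinding("cI_ssrA", K, n, "repressor"),
            expressing=False))
    return PromoterModel(confs)


def _build_c1() -> tuple[CircuitSpec, ParameterSet]:
    p = dict(_C1_PARAMS)
    spec = CircuitSpec(
        name="C1",
        genes=[GeneDescriptor("deGFP", gene_conc=5.0, gene_length=782,
                              protein_length=237,
                              tx_time_constant=p["tau_X_deGFP"],
                              tl_time_constant=p["tau_L_deGFP"])],
        promoters={"deGFP": _p70a(p["dG_deGFP_RNAP"],
                                  p["dG_deGFP_sigma70"],
                                  p["K_deGFP_sigma70"], p["n_deGFP_sigma70"])},
        constitutive_species=[ConstitutiveSpecies("sigma70", 35.0)],
        constants=CharacteristicConstants(tl_saturation=p["K_L"],
                                          capacity_halflife=p["tau_L_half"]),
    )
    return apply_parameters(spec, ParameterSet(p, "C1")), ParameterSet(p, "C1")


def _build_c2() -> tuple[CircuitSpec, ParameterSet]:
    p = dict(_C2_PARAMS)
    genes = [
        GeneDescriptor("sigma28", gene_conc=1.5, gene_length=811,
                       protein_length=240),
        GeneDescriptor("cI_ssrA", gene_conc=1.0, gene_length=850,
                       protein_length=248),
        GeneDescriptor("deGFP_ssrA", gene_conc=8.0, gene_length=782,
                       protein_length=237),
    ]
    promoters = {
        "sigma28": _p70a(p["dG_sigma28_RNAP"], p["dG_sigma28_sigma70"],
                         p["K_sigma28_sigma70"], p["n_sigma28_sigma70"],
                         repressor=(p["dG_sigma28_cI"], p["K_sigma28_cI"],
                                    p["n_sigma28_cI"])),
        "deGFP_ssrA": _p70a(p["dG_deGFP_ssrA_RNAP"],
                            p["dG_deGFP_ssrA_sigma70"],
                            p["K_deGFP_ssrA_sigma70"], p["n_deGFP_ssrA_sigma70"],
                            repressor=(p["dG_deGFP_ssrA_cI"], p["K_deGFP_ssrA_cI"],
                                       p["n_deGFP_ssrA_cI"])),
        "cI_ssrA": PromoterModel([
            PromoterConfiguration("ground", 0.0),
            PromoterConfiguration("RNAP", p["dG_cI_ssrA_RNAP"], expressing=True),
            PromoterConfiguration(
                "RNAP_sigma28", p["dG_cI_ssrA_sigma28"],
                binding=RegulatorBinding("sigma28", p["K_cI_ssrA_sigma28"],
                                         p["n_cI_ssrA_sigma28"], "activator"),
                expressing=True),
        ]),
    }
    spec = CircuitSpec(
        name="C2",
        genes=genes,
        promoters=promoters,
        constitutive_species=[ConstitutiveSpecies("sigma70", 35.0)],
        # sigma28 protein starts at 0: the extract bound (<20 nM) is treated
        # as a ceiling, not an initial value; override via initial_conditions.
        constants=CharacteristicConstants(tl_saturation=p["K_L"],
                                          capacity_halflife=p["tau_L_half"]),
    )
    # seed time constants first so apply_parameters overwrites them
    for g in spec.genes:
        _seed_time_constants(g, spec.constants)
    return apply_parameters(spec, ParameterSet(p, "C2")), ParameterSet(p, "C2")


def builtin_circuit(name: str) -> tuple[CircuitSpec, ParameterSet]:
    """Return (spec, mean estimated parameters) for a built-in circuit.

    ``"C1"`` exposes 11 free parameters, ``"C2"`` 33.
    """
    if name == "C1":
        return _build_c1()
    if name == "C2":
        return _build_c2()
    raise ValueError(f"unknown built-in circuit '{name}' (choose 'C1' or 'C2')")
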