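{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "tcatsim scenario configuration",
  "description": "Scenario files are YAML (JSON accepted) with this structure. 'kind' selects the two-phase 1-D model or the well-mixed three-phase model.",
  "type": "object",
  "required": ["kind", "species", "phases", "solver", "initial"],
  "properties": {
    "kind": {"enum": ["two_phase", "three_phase_0d"]},
    "seed": {"type": "integer", "default": 0},
    "species": {
      "type": "object",
      "required": ["molar_mass"],
      "properties": {
        "molar_mass": {
          "type": "object",
          "description": "species symbol -> molar mass (kg/mol), strictly positive",
          "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
        }
      }
    },
    "phases": {
      "type": "object",
      "description": "phase id ('f','s' for two-phase; 'w','n','s' for three-phase) -> definition",
      "additionalProperties": {
        "type": "object",
        "required": ["members", "reference", "density"],
        "properties": {
          "members": {"type": "array", "items": {"type": "string"}},
          "reference": {"type": "string", "description": "dominant species eliminated by the mass-fraction constraint"},
          "density": {"type": "number", "exclusiveMinimum": 0, "description": "intrinsic density, kg/m^3"},
          "body_potential": {"type": "number", "default": 0, "description": "psi, J/kg, identical for all species in the phase"}
        }
      }
    },
    "thermo": {
      "type": "object",
      "properties": {
        "temperature": {"type": "number", "default": 310.0, "exclusiveMinimum": 0},
        "gas_constant": {"type": "number", "default": 8.314},
        "x_floor": {"type": "number", "default": 1e-12, "exclusiveMinimum": 0, "maximum": 1e-6}
      }
    },
    "mu0": {
      "type": "object",
      "description": "reference chemical potentials, keys '<species>@<phase>', values J/kg",
      "additionalProperties": {"type": "number"}
    },
    "reactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "phase", "stoich", "rate_coeff"],
        "properties": {
          "id": {"type": "string"},
          "phase": {"type": "string"},
          "stoich": {
            "type": "object",
            "description": "species -> signed molar coefficient (reactants negative); must satisfy sum(nu*MW)=0 to 1e-12",
            "additionalProperties": {"type": "number"}
          },
          "rate_coeff": {"type": "number", "minimum": 0},
          "modulations": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["kind", "species"],
              "properties": {
                "kind": {"enum": ["oxygen_switch", "monod"]},
                "species": {"type": "string"},
                "omega_crit": {"type": "number"},
                "delta": {"type": "number", "exclusiveMinimum": 0},
                "half_sat": {"type": "number", "exclusiveMinimum": 0}
              }
            }
          }
        }
      }
    },
    "transfers": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["species", "donor", "receiver", "coeff"],
        "properties": {
          "species": {"type": "string"},
          "donor": {"type": "string"},
          "receiver": {"type": "string"},
          "coeff": {"type": "number", "minimum": 0}
        }
      }
    },
    "closure": {
      "type": "object",
      "properties": {
        "diffusivity": {
          "type": "object",
          "description": "phase -> species -> d_i (m^2/s), nonnegative",
          "additionalProperties": {"additionalProperties": {"type": "number", "minimum": 0}}
        },
        "resistance": {
          "type": "object",
          "description": "fluid phase -> scalar, diagonal or full symmetric PSD tensor (Pa s/m^2)"
        },
        "compressibility": {"type": "number", "minimum": 0},
        "tension": {"type": "object", "additionalProperties": {"type": "number"}},
        "area_relaxation": {"type": "number", "minimum": 0, "description": "khat_wn, 1/s"},
        "capillary_relaxation": {"type": "number", "minimum": 0, "description": "chat_wn, 1/(Pa s)"},
        "area_capillary_coupling": {"type": "number", "minimum": 0, "description": "khat1_wn"},
        "contact_angle": {"type": "number", "description": "rad"}
      }
    },
    "grid": {
      "description": "two-phase only",
      "type": "object",
      "required": ["geometry"],
      "properties": {
        "geometry": {"enum": ["cartesian", "spherical"]},
        "edges": {"type": "array", "items": {"type": "number"}},
        "r_min": {"type": "number"},
        "r_max": {"type": "number"},
        "n_cells": {"type": "integer", "minimum": 1}
      }
    },
    "gravity": {"type": "number", "default": 0, "description": "two-phase only, m/s^2 along +r"},
    "v_solid": {"type": "number", "default": 0, "description": "prescribed constant solid velocity, m/s"},
    "solid_normal_stress": {
      "description": "effective solid normal stress for the porosity diagnostic: 'hydrostatic' (= -p) or a number (Pa)",
      "default": "hydrostatic"
    },
    "include_transfer_momentum": {"type": "boolean", "default": true},
    "initial": {
      "type": "object",
      "description": "two-phase: eps_s, omega_f, omega_s (scalars or per-cell arrays); three-phase: eps_w, eps_n, omega (per phase), eps_wn, curvature_k, pressure_n"
    },
    "boundary": {
      "description": "two-phase only",
      "type": "object",
      "properties": {
        "omega_f_outer": {
          "type": "object",
          "description": "Dirichlet fluid mass fractions at the outer face; absent species are no-flux",
          "additionalProperties": {"type": "number"}
        },
        "pressure_outer": {"type": ["number", "null"], "description": "Dirichlet pressure at the outer face; null = no-flux"},
        "pressure_inner": {"type": ["number", "null"]},
        "gauge_cell": {"type": ["integer", "null"], "description": "required for all-Neumann pressure problems"},
        "gauge_pressure": {"type": "number", "default": 0}
      }
    },
    "geometry": {
      "description": "three-phase only",
      "type": "object",
      "properties": {
        "chi_ws": {"type": "number", "minimum": 0, "maximum": 1},
        "eps_ws": {"type": "number", "minimum": 0},
        "eps_ns": {"type": "number", "minimum": 0},
        "k_ns": {"type": "number"},
        "contact_angle": {"type": "number"},
        "eps_eq_kind": {"enum": ["quadratic", "constant"]},
        "eps_eq_param": {"type": "number"}
      }
    },
    "solver": {
      "type": "object",
      "required": ["t_end"],
      "properties": {
        "t_end": {"type": "number", "exclusiveMinimum": 0},
        "rtol": {"type": "number", "default": 1e-8},
        "atol": {"type": "number", "default": 1e-10},
        "max_step": {"type": "number"},
        "method": {"type": "string", "default": "BDF"},
        "n_out": {"type": "integer", "default": 51, "minimum": 2}
      }
    }
  }
}
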