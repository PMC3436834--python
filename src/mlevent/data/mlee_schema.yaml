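# MLEE task schema: entity and event types, evaluation categories, and the
# argument roles each event type admits.  Ontology cross-references are inert
# metadata (OBO Foundry prefixes); they are never resolved.
#
# Categories drive two things: per-category evaluation report rows, and the
# Theme restriction on event arguments (Anatomical events take Organism or
# Anatomy Themes, Molecular events take Molecule Themes, others any).

entity_types:
  - {name: Organism,                        category: Organism, ontology_refs: ["single cell organism (caro)", "multi-cellular organism (caro)"]}
  - {name: Organism subdivision,            category: Anatomy,  ontology_refs: ["organism subdivision (caro)"]}
  - {name: Anatomical system,               category: Anatomy,  ontology_refs: ["anatomical system (caro)"]}
  - {name: Organ,                           category: Anatomy,  ontology_refs: ["compound organ (caro)"]}
  - {name: Multi-tissue structure,          category: Anatomy,  ontology_refs: ["multi-tissue structure (caro)"]}
  - {name: Tissue,                          category: Anatomy,  ontology_refs: ["portion of tissue (caro)"]}
  - {name: Cell,                            category: Anatomy,  ontology_refs: ["cell (cl)"]}
  - {name: Cellular component,              category: Anatomy,  ontology_refs: ["cellular component (go)"]}
  - {name: Developing anatomical structure, category: Anatomy,  ontology_refs: ["developing anatomical structure (ehdaa)"]}
  - {name: Organism substance,              category: Anatomy,  ontology_refs: ["portion of organism substance (caro)"]}
  - {name: Immaterial anatomical entity,    category: Anatomy,  ontology_refs: ["immaterial anatomical entity (caro)"]}
  - {name: Pathological formation,          category: Anatomy,  ontology_refs: ["cancer (doid)", "benign neoplasm (doid)"]}
  - {name: Drug or compound,                category: Molecule, ontology_refs: ["inorganic molecular entity (chebi)", "drug (chebi)"]}
  - {name: Gene or gene product,            category: Molecule, ontology_refs: ["gene (so)", "RNA (chebi)", "protein (chebi)"]}

event_types:
  - {name: Cell proliferation,       category: Anatomical, roles: [Theme],                        ontology_refs: ["cell proliferation (go)"]}
  - {name: Development,              category: Anatomical, roles: [Theme],                        ontology_refs: ["developmental process (go)"]}
  - {name: Blood vessel development, category: Anatomical, roles: [Theme, AtLoc],                 ontology_refs: ["blood vessel development (go)"]}
  - {name: Growth,                   category: Anatomical, roles: [Theme],                        ontology_refs: ["growth (go)"]}
  - {name: Death,                    category: Anatomical, roles: [Theme],                        ontology_refs: ["death (go)"]}
  - {name: Breakdown,                category: Anatomical, roles: [Theme],                        ontology_refs: []}
  - {name: Remodeling,               category: Anatomical, roles: [Theme],                        ontology_refs: ["tissue remodeling (go)"]}
  - {name: Synthesis,                category: Molecular,  roles: [Theme],                        ontology_refs: ["biosynthetic process (go)"]}
  - {name: Gene expression,          category: Molecular,  roles: [Theme],                        ontology_refs: ["gene expression (go)"]}
  - {name: Transcription,            category: Molecular,  roles: [Theme],                        ontology_refs: ["transcription, DNA-dependent (go)"]}
  - {name: Catabolism,               category: Molecular,  roles: [Theme],                        ontology_refs: ["catabolic process (go)"]}
  - {name: Phosphorylation,          category: Molecular,  roles: [Theme, Site],                  ontology_refs: ["phosphorylation (go)"]}
  - {name: Dephosphorylation,        category: Molecular,  roles: [Theme, Site],                  ontology_refs: ["dephosphorylation (go)"]}
  - {name: Localization,             category: General,    roles: [Theme, AtLoc, FromLoc, ToLoc], ontology_refs: ["localization (go)"]}
  - {name: Binding,                  category: General,    roles: [Theme, Site],                  ontology_refs: ["binding (go)", "biological adhesion (go)"]}
  - {name: Regulation,               category: General,    roles: [Theme, Cause, Site],           ontology_refs: ["biological regulation (go)"]}
  - {name: Positive regulation,      category: General,    roles: [Theme, Cause, Site],           ontology_refs: ["positive regulation of biological process (go)"]}
  - {name: Negative regulation,      category: General,    roles: [Theme, Cause, Site],           ontology_refs: ["negative regulation of biological process (go)"]}
  - {name: Planned process,          category: Planned,    roles: [Theme, Instrument],            ontology_refs: ["planned process (obi)"]}

# Entity categories an entity-valued Theme may carry, by event category.
# Event-valued Themes are unrestricted.  Absent key: unrestricted.
theme_constraints:
  Anatomical: [Organism, Anatomy]
  Molecular: [Molecule]
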