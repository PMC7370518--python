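# Column dictionary for the four delimited EMR extract tables.
#
# One UTF-8 comma-delimited file per table, header row required, missing
# values encoded as the empty string. Dates are ISO-8601 (YYYY-MM-DD);
# patients carry year of birth only (no full birth date).
#
# type: one of str, int, date, bool
# required: column must be present in the file
# nullable: empty string allowed (decoded as missing)
# values: closed vocabulary after normalisation, where applicable

patients:
  patient_id:  {type: str,  required: true, nullable: false, doc: opaque unique identifier}
  birth_year:  {type: int,  required: true, nullable: true,  doc: calendar year of birth}
  gender:      {type: str,  required: true, nullable: true,  values: [M, F], doc: administrative gender; empty = missing/other}
  site_id:     {type: str,  required: true, nullable: true,  doc: clinic identifier}

encounters:
  encounter_id: {type: str,  required: true, nullable: false, doc: "opaque identifier, unique"}
  patient_id:   {type: str,  required: true, nullable: false, doc: reference to patients.patient_id}
  date:         {type: date, required: true, nullable: false, doc: encounter date}
  in_person:    {type: bool, required: true, nullable: false, doc: in-person visit flag}

diagnoses:
  patient_id:   {type: str,  required: true, nullable: false, doc: reference to patients.patient_id}
  encounter_id: {type: str,  required: true, nullable: true,  doc: reference to encounters.encounter_id when linked}
  date:         {type: date, required: true, nullable: false, doc: date the code was recorded}
  code:         {type: str,  required: true, nullable: false, doc: "diagnosis code, stored verbatim (e.g. 314, 314.01)"}
  code_system:  {type: str,  required: true, nullable: false, values: [ICD9]}
  source:       {type: str,  required: true, nullable: false, values: [encounter_diagnosis, billing, health_condition]}

prescriptions:
  patient_id:      {type: str,  required: true, nullable: false, doc: reference to patients.patient_id}
  date:            {type: date, required: true, nullable: false, doc: prescription date}
  drug_identifier: {type: str,  required: true, nullable: false, doc: ATC code or normalised drug name}
  drug_class:      {type: str,  required: true, nullable: true,  doc: "normalised class tag, free vocabulary"}
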