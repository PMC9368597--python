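# Keyword lexicon and sentence templates for restriction-sentence parsing and
# rendering. Editable: site-specific phrasing can be added without touching
# code. Keywords are matched on normalized (lower-cased, symbol-stripped)
# text; tokens of 5+ characters tolerate one edit.
levels:
  MN:
    en: "must not"
    pt: "não pode"
  SN:
    en: "should not"
    pt: "não deve"

regions:
  neck:
    en: [neck]
    pt: [pescoço, cervical]
  trunk:
    en: [trunk]
    pt: [tronco]
  shoulder:
    en: [shoulder, shoulders]
    pt: [ombro, ombros]
  elbow:
    en: [elbow, elbows]
    pt: [cotovelo, cotovelos]
  wrist:
    en: [wrist, wrists]
    pt: [pulso, pulsos, punho, punhos]
  fingers:
    en: [finger, fingers]
    pt: [dedo, dedos]
  knee:
    en: [knee, knees]
    pt: [joelho, joelhos]
  foot:
    en: [foot, feet]
    pt: [pé, pés]

# tokens that carry laterality for a neighbouring region (e.g. "fingers of
# both hands"): treated as transparent carriers, never as regions
carriers:
  en: [hand, hands, line]
  pt: [mão, mãos]

sides:
  left:
    en: [left]
    pt: [esquerdo, esquerda, esquerdos, esquerdas]
  right:
    en: [right]
    pt: [direito, direita, direitos, direitas]
  both:
    en: [both]
    pt: [ambos, ambas]

# process-only restrictions: a protection level with no body part recorded
# (only the occupational physician may assign parts)
process_keywords:
  en: [vibration, "manual material handling"]
  pt: [vibração, "movimentação manual de cargas"]

# --- rendering templates (synthetic corpus) ---------------------------------
sentence_prefix:
  en: "{level} perform tasks that involve {body}."
  pt: "{level} executar tarefas que envolvam {body}."

level_phrases:
  MN: {en: "Must not", pt: "Não pode"}
  SN: {en: "Should not", pt: "Não deve"}

# body phrases keyed by region, then by laterality spec (none/left/right/both)
phrases:
  en:
    neck: {none: "movements of the neck"}
    trunk: {none: "flexion/rotation movements of the trunk"}
    shoulder:
      left: "movements above the left shoulder"
      right: "movements above the right shoulder"
      both: "movements above both shoulders"
    elbow:
      left: "movements of the left elbow"
      right: "movements of the right elbow"
      both: "movements of both elbows"
    wrist:
      left: "rotation movements of the left wrist"
      right: "rotation movements of the right wrist"
      both: "rotation movements of both wrists"
    fingers:
      left: "force with fingers of the left hand"
      right: "force with fingers of the right hand"
      both: "force with fingers of both hands"
    knee:
      left: "flexion movements of the left knee"
      right: "flexion movements of the right knee"
      both: "flexion movements of both knees"
    foot:
      left: "support movements on the left foot"
      right: "support movements on the right foot"
      both: "support movements on both feet"
  pt:
    neck: {none: "movimentos do pescoço"}
    trunk: {none: "movimentos de flexão/rotação do tronco"}
    shoulder:
      left: "movimentos acima do ombro esquerdo"
      right: "movimentos acima do ombro direito"
      both: "movimentos acima de ambos os ombros"
    elbow:
      left: "movimentos do cotovelo esquerdo"
      right: "movimentos do cotovelo direito"
      both: "movimentos de ambos os cotovelos"
    wrist:
      left: "movimentos de rotação do pulso esquerdo"
      right: "movimentos de rotação do pulso direito"
      both: "movimentos de rotação de ambos os pulsos"
    fingers:
      left: "força com os dedos da mão esquerda"
      right: "força com os dedos da mão direita"
      both: "força com os dedos de ambas as mãos"
    knee:
      left: "movimentos de flexão do joelho esquerdo"
      right: "movimentos de flexão do joelho direito"
      both: "movimentos de flexão de ambos os joelhos"
    foot:
      left: "movimentos de apoio no pé esquerdo"
      right: "movimentos de apoio no pé direito"
      both: "movimentos de apoio em ambos os pés"

# full bodies for process-only sentences (no body part recorded)
process_phrases:
  vibration_tools:
    en: "performing tasks using tools with associated vibration"
    pt: "utilizar ferramentas com vibração associada"
  manual_material_handling:
    en: "manual material handling"
    pt: "movimentação manual de cargas"
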