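# Weak extraction rules, one block per information element.
#
# Dialect: standard Python regular expressions extended with entity
# placeholders that match the sentence's annotated entity spans:
#   {integer} {real} {person} {date} {measurement} {unit}
# Fragments are taken from groups named "frag", "frag2", ... (or the whole
# match if no such group exists).  Per rule:
#   take: first | last | all | all_but_last   (which matches yield fragments)
#   ignorecase: case-insensitive matching (default false)
#   require_entity: fragments must overlap an entity span of this kind
#   boost_only: matches boost the candidate score but contribute no
#               highlighted fragments (whole-sentence elements)
# Rules are tried in file order (priority = position); the first rule with a
# match wins.

eligibility_criteria:
  - pattern: '(?P<frag>eligib(?:le|ility)|inclusion criteria|exclusion criteria|were (?:included|excluded)|criteria for (?:inclusion|participation))'
    take: all
    ignorecase: true
    boost_only: true

sample_size:
  - pattern: '(?P<frag>{integer}\s+{person})'
    take: first

start_date_of_enrolment:
  - pattern: '(?P<frag>{date})'
    take: first

end_date_of_enrolment:
  - pattern: '(?P<frag>{date})'
    take: last

experimental_treatment_name:
  - pattern: '\b(?:to receive|received|receiving|with or without|plus either|either|versus|vs\.|plus|or)\s+(?P<frag>(?!(?:the|a|an|to|not|no|without|other|both|either|one|two|all)\b)[a-z][a-z]+(?:\s+acid)?)'
    take: all_but_last

control_treatment_name:
  - pattern: '\b(?:to receive|received|receiving|with or without|plus either|either|versus|vs\.|plus|or)\s+(?P<frag>(?!(?:the|a|an|to|not|no|without|other|both|either|one|two|all)\b)[a-z][a-z]+(?:\s+acid)?)'
    take: last

dose:
  - pattern: '(?P<frag>\d+(?:\.\d+)?\s?(?:mg/kg|mcg|mg|iu|ml|g|units?))(?![\w/])'
    take: all
    ignorecase: true
    require_entity: measurement

frequency_of_treatment:
  - pattern: '(?P<frag>(?:once|twice|three times|four times)\s+(?:daily|a day|per day|weekly|a week|per week)|every\s+\d+\s+(?:days?|weeks?|hours?|months?)|(?:once|twice)\s+(?:a|per)\s+(?:day|week|month))'
    take: all
    ignorecase: true

route_of_treatment:
  - pattern: '(?P<frag>orally|intravenously|subcutaneously|intramuscularly|topically|by mouth|by (?:intravenous )?infusion|by injection)'
    take: all
    ignorecase: true

duration_of_treatment:
  - pattern: '\bfor\s+(?P<frag>{measurement})'
    take: first
    ignorecase: true

primary_outcome_name:
  - pattern: 'primary (?:outcome|end ?point)s?(?: measure)?\s+(?:was|were|is|are)\s+(?:the\s+|defined as\s+)?(?P<frag>[a-z][\w -]{2,60}?)(?=[,.;:]|\s+(?:at|assessed|measured|after|during)\b)'
    take: all
    ignorecase: true

primary_outcome_time_point:
  - pattern: '(?:assessed|measured|evaluated|performed)\s+(?:at|after)\s+(?P<frag>{measurement})'
    take: first
    ignorecase: true
  - pattern: '\bat\s+(?P<frag>{measurement})'
    take: first
    ignorecase: true

secondary_outcome_name:
  - pattern: 'secondary (?:outcome|end ?point)s?(?: measure)?\s+(?:was|were|is|are|included)\s+(?:the\s+|defined as\s+)?(?P<frag>[\w][\w -]{2,60}?)(?=[,.;:]|\s+(?:at|assessed|measured|after|during)\b)'
    take: all
    ignorecase: true

secondary_outcome_time_point:
  - pattern: '(?:assessed|measured|evaluated|performed)\s+(?:at|after)\s+(?P<frag>{measurement})'
    take: first
    ignorecase: true
  - pattern: '\bat\s+(?P<frag>{measurement})'
    take: first
    ignorecase: true

funding_organization_name:
  - pattern: '(?:[Ff]unded|[Ss]upported|[Ss]ponsored)\s+(?:in part\s+)?by(?:\s+(?:a|an)\s+(?:research\s+)?grant\s+from)?\s+(?:the\s+)?(?P<frag>[A-Z][\w&.-]*(?:(?:\s+(?:of|for|and|the))*\s+[A-Z][\w&.-]*)*)'
    take: all
  - pattern: '[Gg]rants?\s+\S+\s+from\s+(?:the\s+)?(?P<frag>[A-Z][\w&.-]*(?:(?:\s+(?:of|for|and|the))*\s+[A-Z][\w&.-]*)*)'
    take: all

funding_number:
  - pattern: '(?:[Gg]rants?(?:\s+(?:numbers?|[Nn]os?\.|#))?|[Aa]ward(?:\s+number)?)\s+(?P<frag>[A-Z0-9][A-Za-z0-9/.-]{2,})'
    take: all

early_stopping:
  - pattern: '(?P<frag>(?:stopped|terminated|halted|discontinued)\s+(?:early|prematurely)|early\s+(?:stopping|termination)|stopped\s+the\s+trial\s+early)'
    take: first
    ignorecase: true

trial_registration_id:
  - pattern: '(?P<frag>(?:NCT|ISRCTN)\d{6,8})'
    take: first
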