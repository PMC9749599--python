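- code_a: head
  code_b: head
  relatedness: 1.0
  affinal: false
- code_a: head
  code_b: spouse
  relatedness: 0.0
  affinal: true
- code_a: head
  code_b: son_daughter
  relatedness: 0.5
  affinal: false
- code_a: head
  code_b: son_daughter_in_law
  relatedness: 0.0
  affinal: true
- code_a: head
  code_b: grandchild
  relatedness: 0.25
  affinal: false
- code_a: head
  code_b: parent
  relatedness: 0.5
  affinal: false
- code_a: head
  code_b: parent_in_law
  relatedness: 0.0
  affinal: true
- code_a: head
  code_b: sibling
  relatedness: 0.5
  affinal: false
- code_a: head
  code_b: niece_nephew
  relatedness: 0.125
  affinal: false
- code_a: head
  code_b: other_relative
  relatedness: 0.125
  affinal: false
- code_a: head
  code_b: adopted_foster
  relatedness: 0.0
  affinal: true
- code_a: spouse
  code_b: son_daughter
  relatedness: 0.5
  affinal: false
- code_a: spouse
  code_b: son_daughter_in_law
  relatedness: 0.0
  affinal: true
- code_a: spouse
  code_b: grandchild
  relatedness: 0.25
  affinal: false
- code_a: spouse
  code_b: parent
  relatedness: 0.0
  affinal: true
- code_a: spouse
  code_b: parent_in_law
  relatedness: 0.5
  affinal: false
- code_a: spouse
  code_b: adopted_foster
  relatedness: 0.0
  affinal: true
- code_a: son_daughter
  code_b: son_daughter
  relatedness: 0.5
  affinal: false
- code_a: son_daughter
  code_b: son_daughter_in_law
  relatedness: 0.0
  affinal: true
- code_a: son_daughter
  code_b: grandchild
  relatedness: 0.25
  affinal: false
- code_a: son_daughter
  code_b: parent
  relatedness: 0.25
  affinal: false
- code_a: son_daughter
  code_b: parent_in_law
  relatedness: 0.25
  affinal: false
- code_a: son_daughter
  code_b: sibling
  relatedness: 0.125
  affinal: false
- code_a: son_daughter
  code_b: niece_nephew
  relatedness: 0.125
  affinal: false
- code_a: son_daughter
  code_b: adopted_foster
  relatedness: 0.0
  affinal: true
- code_a: son_daughter_in_law
  code_b: grandchild
  relatedness: 0.5
  affinal: false
- code_a: grandchild
  code_b: grandchild
  relatedness: 0.25
  affinal: false
- code_a: grandchild
  code_b: parent
  relatedness: 0.125
  affinal: false
- code_a: grandchild
  code_b: parent_in_law
  relatedness: 0.125
  affinal: false
- code_a: grandchild
  code_b: sibling
  relatedness: 0.125
  affinal: false
- code_a: grandchild
  code_b: niece_nephew
  relatedness: 0.125
  affinal: false
- code_a: parent
  code_b: parent
  relatedness: 0.0
  affinal: true
- code_a: parent
  code_b: sibling
  relatedness: 0.5
  affinal: false
- code_a: parent
  code_b: niece_nephew
  relatedness: 0.25
  affinal: false
- code_a: parent_in_law
  code_b: parent_in_law
  relatedness: 0.0
  affinal: true
- code_a: sibling
  code_b: sibling
  relatedness: 0.5
  affinal: false
- code_a: sibling
  code_b: niece_nephew
  relatedness: 0.25
  affinal: false
- code_a: niece_nephew
  code_b: niece_nephew
  relatedness: 0.25
  affinal: false
- code_a: adopted_foster
  code_b: adopted_foster
  relatedness: 0.0
  affinal: true
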