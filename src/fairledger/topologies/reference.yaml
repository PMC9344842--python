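# Reference consortium: three organizations in one channel, two EVC
# nodes each, one orderer, three storage nodes per organization (nine
# devices, enough for the default 4+4 erasure geometry).
consortium: hub-consortium
channel: fiber-channel
organizations:
  - org_id: org-london
    domain: ic.ac.uk
    evc_nodes: 2
    storage_nodes: 3
  - org_id: org-oslo
    domain: ous.no
    evc_nodes: 2
    storage_nodes: 3
  - org_id: org-bergen
    domain: nrec.no
    evc_nodes: 2
    storage_nodes: 3
storage:
  data_shards: 4
  parity_shards: 4
users:
  - user_id: alice
    org_id: org-oslo
    secret: alginate-fiber
    admin: true
  - user_id: bob
    org_id: org-london
    secret: collagen-gel
    admin: false
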