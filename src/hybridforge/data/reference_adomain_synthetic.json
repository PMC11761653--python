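{
 "name": "synthetic_adomain_reference",
 "description": "Synthetic stand-in reference A-domain scaffold. Position conventions follow GrsA-style numbering for the 10 binding-pocket (Stachelhaus) residues; the 34 signature positions are a superset of the 10. Users may supply a real reference (e.g. the GrsA Phe-activating A-domain) in the same schema.",
 "reference_sequence": "CLKHKVRLHYYERMHVWLCCNGVAGACQLDKQHDQDEFFHRTPAKEFVGCYTADNWDSMWCWKCPEYTQMTGAYQMWTCTDISRCWPFRSVGKPGGDSFAERGRRWMIWTQYEYRAIMCPYMNSLDCWCRSNVKRKWKLMKKWGYEHRKVVFKDSIKAENSKLGVLIMMGFNAIFFVRYALYVNETAVTKMGDPAACWITQPTMCMVNGWWDFKYDPPQLVPQDKFKKKRVCSNILHLVPRTWPMNVHVHDSMRSHVFMWVWTPLMRADQQRSIGPSQQQNTVPKETYEGRQHWWVWSRNNKKLNYCTINDYRHHDTTHPVHGFPVRRNQTSQDFEWVQIYTWCILPGWNHVGFNIRATFFAGGLPWCDCHATTFPGQPTIPTTCCVGKMQRHYANEFLPLMEDQFFAYSRIAGPEFVNTSFKGWMQTPWVMNNVPNKMIWNGGFLWSIHFEHRREIIYIGNAVVHYIKQNANPDAKAPPFVASISRPSSQIVERCDTLQNICQSRRFHMQWNRVYKYSA",
 "stachelhaus_positions": [
  234,
  235,
  238,
  277,
  298,
  300,
  321,
  329,
  330,
  516
 ],
 "signature_positions": [
  229,
  231,
  232,
  234,
  235,
  238,
  240,
  243,
  275,
  276,
  277,
  279,
  296,
  297,
  298,
  300,
  302,
  305,
  318,
  319,
  321,
  323,
  325,
  327,
  329,
  330,
  332,
  334,
  336,
  413,
  414,
  420,
  515,
  516
 ],
 "version": 1
}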