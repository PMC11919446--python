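// In-place toggling and navigation: no network access, no external state.
document.addEventListener("DOMContentLoaded", function () {
  document.querySelectorAll("button.toggle").forEach(function (btn) {
    btn.addEventListener("click", function () {
      var target = document.getElementById(btn.dataset.target);
      if (target) {
        target.classList.toggle("shown");
      }
    });
  });
  // support tap-to-open dropdowns on touch devices
  document.querySelectorAll(".dropdown > button").forEach(function (btn) {
    btn.addEventListener("click", function () {
      btn.parentElement.classList.toggle("open");
    });
  });
});
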